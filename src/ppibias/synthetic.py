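"""Synthetic interaction datasets with controllable per-protein positivity
bias, plus matching synthetic embeddings.

The generator emulates the structure of real PPI benchmarks that inflates
randomly-split evaluation: a skewed per-protein positivity distribution
(many proteins strongly biased toward positive or negative partners, a
configurable fraction purely one class), a heavy-tailed degree
distribution, and a globally near-balanced label distribution.  Labels for
a pair (i, j) are drawn as::

    label ~ Bernoulli( lam * sigmoid(z_i . z_j) + (1 - lam) * (p_i + p_j) / 2 )

where ``p_i`` is protein i's target positivity, ``z_i`` its latent
interaction vector and ``lam`` (``signal_weight``) mixes identity-driven
and latent-signal-driven labels.  With ``lam = 0`` the labels carry no
information beyond protein identity; with ``lam = 1`` they are driven by a
latent geometry that feature-based classifiers can genuinely learn.

Embeddings come in two modes: ``identity`` vectors are a deterministic
pseudorandom function of (protein id, seed) and carry no label signal
beyond identifying the protein; ``signal`` vectors expose the latent
vectors (plus Gaussian noise) in their leading coordinates.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.special import expit

from ppibias.data_model import Interaction, InteractionDataset
from ppibias.features import EmbeddingStore


@dataclass(frozen=True)
class BiasSpec:
    """Parameters of the biased-dataset generator.

    ``frac_pure`` of the proteins get a target positivity forced to exactly
    1 or 0; ``pure_positive_share`` controls how that fraction splits
    between pure-positive and pure-negative (0.5 = even).  The remaining
    proteins draw their target positivity from Beta(beta_a, beta_b).
    Endpoints are sampled proportionally to a heavy-tailed degree weight
    ``rank^(-degree_exponent)``.

    ``homophily`` in [0, 1] optionally biases partner choice toward proteins
    of similar target positivity (similar proteins sharing partner
    networks): with probability ``homophily`` the second endpoint is drawn
    with its degree weight damped by a Gaussian kernel in positivity space.
    At 0 (default) partners are positivity-independent, which plants
    residual within-protein partner signal a random-split learner can
    legitimately recover; near 1 the label probability becomes conditionally
    constant per protein, isolating pure identity bias.
    """

    n_proteins: int = 500
    n_interactions: int = 10_000
    frac_pure: float = 0.15
    pure_positive_share: float = 0.5
    beta_a: float = 0.3
    beta_b: float = 0.3
    signal_weight: float = 0.0
    latent_dim: int = 8
    degree_exponent: float = 0.8
    homophily: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise ValueError("need at least 2 proteins")
        if not 0.0 <= self.frac_pure <= 1.0:
            raise ValueError("frac_pure must be in [0, 1]")
        if not 0.0 <= self.pure_positive_share <= 1.0:
            raise ValueError("pure_positive_share must be in [0, 1]")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("beta shape parameters must be positive")
        if not 0.0 <= self.signal_weight <= 1.0:
            raise ValueError("signal_weight must be in [0, 1]")
        if not 0.0 <= self.homophily <= 1.0:
            raise ValueError("homophily must be in [0, 1]")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        max_pairs = self.n_proteins * (self.n_proteins - 1) // 2
        if self.n_interactions < self.n_proteins:
            raise ValueError(
                "infeasible spec: n_interactions must be >= n_proteins so every "
                "protein can appear in at least one interaction"
            )
        if self.n_interactions > max_pairs:
            raise ValueError(
                f"infeasible spec: {self.n_interactions} distinct pairs requested "
                f"but only {max_pairs} exist"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BiasSpec":
        return cls(**d)


@dataclass
class GroundTruth:
    """The generator's latent state, kept for parameter-recovery tests."""

    proteins: list[str]
    positivity: np.ndarray  # target p_i per protein, same order as proteins
    latent: np.ndarray  # (n_proteins, latent_dim) latent vectors z_i
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {p: i for i, p in enumerate(self.proteins)}


def _protein_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"P{i:0{width}d}" for i in range(n)]


def generate_dataset(spec: BiasSpec) -> tuple[InteractionDataset, GroundTruth]:
    """Generate a biased interaction dataset; reproducible from the seed.

    Pairs are distinct (no duplicates, no self-pairs).  A first pass pairs
    shuffled proteins consecutively so every protein appears in at least one
    interaction; the rest are drawn with endpoint probabilities proportional
    to the heavy-tailed degree weights, resampling on collision.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    proteins = _protein_names(n)

    # per-protein target positivity
    p = rng.beta(spec.beta_a, spec.beta_b, size=n)
    n_pure = int(round(spec.frac_pure * n))
    if n_pure:
        pure_idx = rng.choice(n, size=n_pure, replace=False)
        n_pure_pos = int(round(spec.pure_positive_share * n_pure))
        p[pure_idx[:n_pure_pos]] = 1.0
        p[pure_idx[n_pure_pos:]] = 0.0

    # latent interaction vectors
    z = rng.standard_normal((n, spec.latent_dim))

    # heavy-tailed degree weights over a random rank assignment
    ranks = rng.permutation(n) + 1
    weights = ranks.astype(float) ** (-spec.degree_exponent)
    weights /= weights.sum()

    pairs: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()

    def _add(i: int, j: int) -> bool:
        key = (i, j) if i < j else (j, i)
        if i == j or key in seen:
            return False
        seen.add(key)
        pairs.append((i, j))
        return True

    # coverage pass: consecutive pairs of a shuffled order touch everyone
    order = rng.permutation(n)
    for k in range(0, n - 1, 2):
        _add(int(order[k]), int(order[k + 1]))
    if n % 2 == 1:
        _add(int(order[-1]), int(order[0]))

    # weighted sampling for the remainder
    if spec.homophily > 0.0:
        # kernel bandwidth in positivity space; 0.05 makes partners of a
        # strongly homophilous draw nearly iso-positivity
        inv_two_tau_sq = 1.0 / (2.0 * 0.05**2)
        while len(pairs) < spec.n_interactions:
            i = int(rng.choice(n, p=weights))
            if rng.random() < spec.homophily:
                w = weights * np.exp(-((p - p[i]) ** 2) * inv_two_tau_sq)
                w[i] = 0.0
                total = w.sum()
                if total <= 0.0:
                    continue
                j = int(rng.choice(n, p=w / total))
            else:
                j = int(rng.choice(n, p=weights))
            _add(i, j)
    else:
        while len(pairs) < spec.n_interactions:
            need = spec.n_interactions - len(pairs)
            batch = max(64, int(need * 1.5))
            ii = rng.choice(n, size=batch, p=weights)
            jj = rng.choice(n, size=batch, p=weights)
            for i, j in zip(ii, jj):
                if _add(int(i), int(j)) and len(pairs) == spec.n_interactions:
                    break

    lam = spec.signal_weight
    records: list[Interaction] = []
    for i, j in pairs:
        prob = lam * expit(float(z[i] @ z[j])) + (1.0 - lam) * (p[i] + p[j]) / 2.0
        label = int(rng.random() < prob)
        records.append(Interaction(proteins[i], proteins[j], label))

    ds = InteractionDataset.from_records(
        records, on_duplicate="error", provenance={"generator": spec.to_dict()}
    )
    truth = GroundTruth(proteins=proteins, positivity=p, latent=z)
    return ds, truth


def _protein_rng(pid: str, seed: int) -> np.random.Generator:
    # stable across processes/runs: derive entropy from a keyed hash
    digest = hashlib.blake2b(f"{seed}|{pid}".encode(), digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(digest, "big"))


def generate_embeddings(
    proteins,
    mode: str,
    dim: int,
    *,
    noise_sd: float = 0.1,
    truth: GroundTruth | None = None,
    seed: int = 0,
) -> EmbeddingStore:
    """Synthetic per-protein embeddings.

    ``identity`` mode: each vector is a deterministic pseudorandom function
    of (protein id, seed), independent of any labels — it identifies the
    protein but carries no interaction signal.  ``signal`` mode: the first
    ``latent_dim`` coordinates are the protein's latent vector plus Gaussian
    noise of scale ``noise_sd``; remaining coordinates are pseudorandom
    filler.  Same inputs produce bit-identical output.
    """
    if mode not in ("identity", "signal"):
        raise ValueError(f"unknown embedding mode {mode!r}")
    if mode == "signal":
        if truth is None:
            raise ValueError("signal mode requires the generator GroundTruth")
        latent_dim = truth.latent.shape[1]
        if dim < latent_dim:
            raise ValueError(
                f"dim={dim} is smaller than the latent dimension {latent_dim}"
            )
    vectors: dict[str, np.ndarray] = {}
    for pid in proteins:
        rng = _protein_rng(pid, seed)
        vec = rng.standard_normal(dim)
        if mode == "signal":
            z = truth.latent[truth.index[pid]]
            noise = rng.standard_normal(len(z)) * noise_sd if noise_sd else 0.0
            vec[: len(z)] = z + noise
        vectors[pid] = vec
    return EmbeddingStore(vectors)
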