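"""Random interaction folds, unseen-protein folds and nested CV plans.

Unseen-protein folds start from a plain random partition; for each fold the
validation protein set (both endpoints of every validation interaction) is
computed and every training interaction touching that set is removed.  The
training set therefore shrinks, which is why unseen-protein evaluation uses
many more, smaller folds than the random regime to keep per-iteration
training sizes comparable (defaults: random 3 outer / 3 inner, unseen 50
outer / 40 inner).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ppibias.data_model import InteractionDataset

MODES = ("random", "unseen_protein")

#: default (k_outer, k_inner) per split mode
DEFAULT_FOLDS = {"random": (3, 3), "unseen_protein": (50, 40)}


class SplitError(ValueError):
    pass


@dataclass(frozen=True)
class Fold:
    """Disjoint train/validation interaction index sets."""

    train_idx: tuple[int, ...]
    valid_idx: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.train_idx) & set(self.valid_idx):
            raise SplitError("train and validation indices overlap")

    @property
    def n_train(self) -> int:
        return len(self.train_idx)

    @property
    def n_valid(self) -> int:
        return len(self.valid_idx)


def fold_proteins(ds: InteractionDataset, indices: tuple[int, ...]) -> frozenset[str]:
    """All endpoint proteins of the given interaction indices."""
    out: set[str] = set()
    for i in indices:
        it = ds.interactions[i]
        out.add(it.protein_a)
        out.add(it.protein_b)
    return frozenset(out)


def _partition(indices: np.ndarray, k: int) -> list[np.ndarray]:
    # remainder spread one-per-fold starting from the first fold
    n = len(indices)
    base, rem = divmod(n, k)
    parts, start = [], 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        parts.append(indices[start : start + size])
        start += size
    return parts


def random_folds(ds: InteractionDataset | int, k: int, seed: int) -> list[Fold]:
    """Shuffle interaction indices by ``seed`` and partition into ``k``
    near-equal validation sets; each fold trains on the complement.

    ``k=1`` is allowed only for testing and yields a single fold with an
    empty training set.
    """
    n = ds if isinstance(ds, int) else len(ds)
    if k < 1:
        raise SplitError(f"k must be >= 1, got {k}")
    if k > n:
        raise SplitError(f"k={k} exceeds the number of interactions ({n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    parts = _partition(order, k)
    folds = []
    all_idx = set(range(n))
    for part in parts:
        valid = set(int(i) for i in part)
        train = sorted(all_idx - valid)
        folds.append(Fold(train_idx=tuple(train), valid_idx=tuple(sorted(valid))))
    return folds


def unseen_protein_folds(ds: InteractionDataset, k: int, seed: int) -> list[Fold]:
    """Random folds with all training interactions touching any validation
    protein removed, so no protein appears on both sides of a fold."""
    folds = random_folds(ds, k, seed)
    out = []
    for fold in folds:
        vp = fold_proteins(ds, fold.valid_idx)
        kept = tuple(
            i
            for i in fold.train_idx
            if ds.interactions[i].protein_a not in vp
            and ds.interactions[i].protein_b not in vp
        )
        if not kept and fold.train_idx:
            raise SplitError(
                "unseen-protein filtering removed every training interaction "
                f"in a fold (validation touches {len(vp)} proteins); "
                "use a larger k so each validation partition is smaller"
            )
        out.append(Fold(train_idx=kept, valid_idx=fold.valid_idx))
    return out


def retained_training_fraction(random: list[Fold], unseen: list[Fold]) -> float:
    """Mean fraction of random-fold training interactions surviving the
    unseen-protein filter (diagnostic for fold-count choice)."""
    fracs = [
        u.n_train / r.n_train for r, u in zip(random, unseen) if r.n_train
    ]
    return float(np.mean(fracs)) if fracs else 0.0


@dataclass
class FoldPlan:
    """A nested cross-validation layout.

    ``outer[i]`` holds the i-th outer train/validation split; ``inner[i]``
    holds the inner folds built *from that outer fold's training indices
    only* (hyperparameter selection never sees outer validation data).
    Inner folds use the same split mode as the outer folds, so in
    unseen-protein mode hyperparameters are selected under the same regime
    they are evaluated in.
    """

    mode: str
    outer: list[Fold]
    inner: list[list[Fold]]
    seed: int
    k_outer: int
    k_inner: int

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise SplitError(f"unknown split mode {self.mode!r}")
        if len(self.inner) != len(self.outer):
            raise SplitError("one inner fold list required per outer fold")


def _child_seed(seed: int, outer_index: int) -> int:
    return int(np.random.SeedSequence([seed, outer_index]).generate_state(1)[0])


def _subset_dataset(ds: InteractionDataset, indices: tuple[int, ...]) -> InteractionDataset:
    return InteractionDataset(
        interactions=[ds.interactions[i] for i in indices],
        provenance={"subset_of": ds.provenance.get("path", "<memory>")},
    )


def make_plan(
    ds: InteractionDataset,
    mode: str,
    k_outer: int | None = None,
    k_inner: int | None = None,
    seed: int = 0,
) -> FoldPlan:
    """Build a nested CV plan; inner folds reuse the outer fold's mode.

    Fold-count defaults are ``DEFAULT_FOLDS[mode]`` — random 3/3, unseen
    50/40, chosen upstream so both regimes train on similar numbers of
    interactions per iteration.
    """
    if mode not in MODES:
        raise SplitError(f"unknown split mode {mode!r}; expected one of {MODES}")
    default_outer, default_inner = DEFAULT_FOLDS[mode]
    k_outer = default_outer if k_outer is None else k_outer
    k_inner = default_inner if k_inner is None else k_inner

    constructor = random_folds if mode == "random" else unseen_protein_folds
    outer = constructor(ds, k_outer, seed)

    inner: list[list[Fold]] = []
    for i, fold in enumerate(outer):
        sub = _subset_dataset(ds, fold.train_idx)
        local = constructor(sub, k_inner, _child_seed(seed, i))
        # map local (subset) positions back to global interaction indices
        mapping = fold.train_idx
        inner.append(
            [
                Fold(
                    train_idx=tuple(mapping[j] for j in f.train_idx),
                    valid_idx=tuple(mapping[j] for j in f.valid_idx),
                )
                for f in local
            ]
        )
    return FoldPlan(
        mode=mode, outer=outer, inner=inner, seed=seed, k_outer=k_outer, k_inner=k_inner
    )


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------

def plan_to_text(plan: FoldPlan, path: str | Path) -> None:
    """One line per fold: ``<scope> <outer_id> [<inner_id>] <role> <indices>``."""
    with Path(path).open("w") as fh:
        fh.write(f"# mode={plan.mode} seed={plan.seed} "
                 f"k_outer={plan.k_outer} k_inner={plan.k_inner}\n")
        for i, fold in enumerate(plan.outer):
            fh.write(f"outer {i} train {' '.join(map(str, fold.train_idx))}\n")
            fh.write(f"outer {i} valid {' '.join(map(str, fold.valid_idx))}\n")
            for j, inner in enumerate(plan.inner[i]):
                fh.write(f"inner {i} {j} train {' '.join(map(str, inner.train_idx))}\n")
                fh.write(f"inner {i} {j} valid {' '.join(map(str, inner.valid_idx))}\n")


def plan_from_text(path: str | Path) -> FoldPlan:
    header: dict[str, str] = {}
    outer_parts: dict[int, dict[str, tuple[int, ...]]] = {}
    inner_parts: dict[tuple[int, int], dict[str, tuple[int, ...]]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        header[k] = v
                continue
            fields = line.split()
            if fields[0] == "outer":
                i, role = int(fields[1]), fields[2]
                idx = tuple(int(x) for x in fields[3:])
                outer_parts.setdefault(i, {})[role] = idx
            elif fields[0] == "inner":
                i, j, role = int(fields[1]), int(fields[2]), fields[3]
                idx = tuple(int(x) for x in fields[4:])
                inner_parts.setdefault((i, j), {})[role] = idx
            else:
                raise SplitError(f"unrecognised plan line: {line!r}")
    outer = [
        Fold(train_idx=outer_parts[i].get("train", ()), valid_idx=outer_parts[i]["valid"])
        for i in sorted(outer_parts)
    ]
    inner: list[list[Fold]] = [[] for _ in outer]
    for (i, j) in sorted(inner_parts):
        parts = inner_parts[(i, j)]
        inner[i].append(Fold(train_idx=parts.get("train", ()), valid_idx=parts["valid"]))
    return FoldPlan(
        mode=header.get("mode", "random"),
        outer=outer,
        inner=inner,
        seed=int(header.get("seed", 0)),
        k_outer=int(header.get("k_outer", len(outer))),
        k_inner=int(header.get("k_inner", max((len(f) for f in inner), default=0))),
    )
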