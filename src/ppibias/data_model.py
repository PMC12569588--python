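"""Core data types and I/O for labeled protein-pair datasets.

An interaction dataset is an ordered list of labeled protein pairs.  Pairs
are stored as given (``(A, B)`` is not canonicalised to ``(B, A)``) because
downstream pair-feature combination distinguishes orientation.  Labels are
held internally as integers: ``1`` for positive (interacting), ``0`` for
negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

POSITIVE = 1
NEGATIVE = 0

#: label tokens accepted by :func:`read_interactions` (case-insensitive)
DEFAULT_LABEL_TOKENS: Mapping[str, int] = {
    "1": POSITIVE,
    "0": NEGATIVE,
    "positive": POSITIVE,
    "negative": NEGATIVE,
    "true": POSITIVE,
    "false": NEGATIVE,
}


class DatasetError(ValueError):
    """Base class for dataset construction/parsing failures."""


class ParseError(DatasetError):
    """A malformed row; the message names the offending line number."""


class LabelError(ParseError):
    """An unrecognised label token."""


class DuplicateInteractionError(DatasetError):
    """Exact duplicate rows (or same ordered pair with conflicting labels)."""


@dataclass(frozen=True)
class Interaction:
    """One labeled ordered protein pair."""

    protein_a: str
    protein_b: str
    label: int

    def __post_init__(self) -> None:
        if not self.protein_a or not self.protein_b:
            raise DatasetError("protein identifiers must be non-empty")
        if self.label not in (POSITIVE, NEGATIVE):
            raise DatasetError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def is_self(self) -> bool:
        return self.protein_a == self.protein_b

    @property
    def proteins(self) -> tuple[str, ...]:
        """Distinct endpoints (one element for a self-interaction)."""
        if self.is_self:
            return (self.protein_a,)
        return (self.protein_a, self.protein_b)


@dataclass
class InteractionDataset:
    """An ordered collection of interactions plus the protein universe.

    Parameters
    ----------
    interactions
        The records, in file/generation order.
    sequences
        Optional mapping from protein identifier to amino-acid sequence.
    provenance
        Free-form record of where the data came from (path, dialect,
        deduplication policy, generator spec, ...).
    """

    interactions: list[Interaction]
    sequences: dict[str, str] | None = None
    provenance: dict = field(default_factory=dict)
    proteins: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.proteins = frozenset(
            p for it in self.interactions for p in (it.protein_a, it.protein_b)
        )

    def __len__(self) -> int:
        return len(self.interactions)

    def __iter__(self):
        return iter(self.interactions)

    @property
    def n_positive(self) -> int:
        return sum(it.label == POSITIVE for it in self.interactions)

    @property
    def n_negative(self) -> int:
        return len(self.interactions) - self.n_positive

    @classmethod
    def from_records(
        cls,
        records: Iterable[Interaction],
        *,
        on_duplicate: str = "error",
        sequences: dict[str, str] | None = None,
        provenance: dict | None = None,
    ) -> "InteractionDataset":
        """Build a dataset enforcing the duplicate policy.

        ``on_duplicate`` is ``"error"`` (default: exact duplicates rejected)
        or ``"dedup"`` (keep first occurrence).  A repeated ordered pair with
        *conflicting* labels is always an error: silently keeping either row
        would distort per-protein weights.
        """
        if on_duplicate not in ("error", "dedup"):
            raise ValueError(f"unknown duplicate policy {on_duplicate!r}")
        seen: dict[tuple[str, str], int] = {}
        kept: list[Interaction] = []
        for it in records:
            key = (it.protein_a, it.protein_b)
            if key in seen:
                if seen[key] != it.label:
                    raise DuplicateInteractionError(
                        f"conflicting labels for pair {key}"
                    )
                if on_duplicate == "error":
                    raise DuplicateInteractionError(
                        f"exact duplicate row for pair {key}"
                    )
                continue  # dedup: keep first
            seen[key] = it.label
            kept.append(it)
        prov = dict(provenance or {})
        prov.setdefault("dedup_policy", on_duplicate)
        return cls(interactions=kept, sequences=sequences, provenance=prov)


@dataclass(frozen=True)
class ProteinStats:
    """Per-protein interaction counts and positivity (fraction positive)."""

    protein: str
    n_pos: int
    n_neg: int

    @property
    def n_total(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def positivity(self) -> float:
        return self.n_pos / self.n_total


@dataclass(frozen=True)
class DatasetSummary:
    n_proteins: int
    n_interactions: int
    n_positive: int
    n_negative: int
    n_only_positive_proteins: int
    n_only_negative_proteins: int
    n_mixed_proteins: int

    @property
    def pct_single_class(self) -> float:
        """Percentage of proteins whose interactions are all one class."""
        return pct_single_class(
            self.n_only_positive_proteins,
            self.n_only_negative_proteins,
            self.n_proteins,
        )


def pct_single_class(n_only_positive: int, n_only_negative: int, n_proteins: int) -> float:
    """``100 * (only_positive + only_negative) / n_proteins`` in percent."""
    if n_proteins <= 0:
        raise ValueError("n_proteins must be positive")
    return 100.0 * (n_only_positive + n_only_negative) / n_proteins


def summarize(ds: InteractionDataset) -> tuple[DatasetSummary, list[ProteinStats]]:
    """Dataset-level and per-protein composition statistics.

    Every interaction contributes to the stats of *both* endpoint proteins;
    a self-interaction contributes once.
    """
    if len(ds) == 0:
        raise DatasetError("cannot summarize an empty dataset")
    pos: dict[str, int] = {}
    neg: dict[str, int] = {}
    for it in ds:
        for p in it.proteins:
            if it.label == POSITIVE:
                pos[p] = pos.get(p, 0) + 1
                neg.setdefault(p, 0)
            else:
                neg[p] = neg.get(p, 0) + 1
                pos.setdefault(p, 0)
    stats = [ProteinStats(p, pos[p], neg[p]) for p in sorted(pos)]
    only_pos = sum(1 for s in stats if s.n_neg == 0)
    only_neg = sum(1 for s in stats if s.n_pos == 0)
    summary = DatasetSummary(
        n_proteins=len(stats),
        n_interactions=len(ds),
        n_positive=ds.n_positive,
        n_negative=ds.n_negative,
        n_only_positive_proteins=only_pos,
        n_only_negative_proteins=only_neg,
        n_mixed_proteins=len(stats) - only_pos - only_neg,
    )
    return summary, stats


# ---------------------------------------------------------------------------
# interaction table I/O
# ---------------------------------------------------------------------------

def _parse_label(token: str, label_tokens: Mapping[str, int], lineno: int) -> int:
    try:
        return label_tokens[token.strip().lower()]
    except KeyError:
        raise LabelError(
            f"line {lineno}: unknown label token {token.strip()!r}"
        ) from None


def read_interactions(
    path: str | Path,
    *,
    sep: str = "\t",
    header: bool | str = "auto",
    label_tokens: Mapping[str, int] = DEFAULT_LABEL_TOKENS,
    on_duplicate: str = "error",
) -> InteractionDataset:
    """Read a labeled interaction table: ``protein_a<sep>protein_b<sep>label``.

    ``header`` may be ``True``, ``False`` or ``"auto"`` (skip the first row
    iff its third field is not a recognised label token).  Extra columns are
    ignored.  An empty file yields an empty dataset with a logged warning.
    """
    path = Path(path)
    rows: list[tuple[int, list[str]]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            rows.append((lineno, line.split(sep)))

    if not rows:
        logger.warning("interaction file %s is empty", path)
        return InteractionDataset.from_records(
            [], on_duplicate=on_duplicate, provenance={"path": str(path), "sep": sep}
        )

    start = 0
    if header is True:
        start = 1
    elif header == "auto":
        first_fields = rows[0][1]
        if len(first_fields) < 3 or first_fields[2].strip().lower() not in label_tokens:
            start = 1

    records: list[Interaction] = []
    for lineno, fields in rows[start:]:
        if len(fields) < 3:
            raise ParseError(
                f"line {lineno}: expected at least 3 fields, got {len(fields)}"
            )
        a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            raise ParseError(f"line {lineno}: empty protein identifier")
        label = _parse_label(fields[2], label_tokens, lineno)
        records.append(Interaction(a, b, label))

    return InteractionDataset.from_records(
        records,
        on_duplicate=on_duplicate,
        provenance={"path": str(path), "sep": sep, "header_skipped": bool(start)},
    )


def write_interactions(
    ds: InteractionDataset, path: str | Path, *, sep: str = "\t", header: bool = True
) -> None:
    """Write the standard interaction table (labels as 1/0)."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write(sep.join(("protein_a", "protein_b", "label")) + "\n")
        for it in ds:
            fh.write(sep.join((it.protein_a, it.protein_b, str(it.label))) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by the header token before whitespace.

    Sequences are uppercased.  Duplicate identifiers and sequence data
    before the first header are errors.
    """
    path = Path(path)
    with path.open() as fh:
        for line in fh:
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise DatasetError(
                    f"{path}: sequence data before first FASTA header"
                )
            break
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise DatasetError(f"{path}: duplicate FASTA identifier {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return sequences


# ---------------------------------------------------------------------------
# gold-standard distribution
# ---------------------------------------------------------------------------

@dataclass
class GoldStandard:
    """A leakage-free train/validation/test distribution plus sequences."""

    train: InteractionDataset
    validation: InteractionDataset
    test: InteractionDataset
    sequences: dict[str, str]
    #: proteins shared between partitions, keyed by partition-pair name
    overlaps: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def is_protein_disjoint(self) -> bool:
        return all(not v for v in self.overlaps.values())


def load_gold_standard(
    directory: str | Path,
    *,
    train_file: str = "train.tsv",
    validation_file: str = "validation.tsv",
    test_file: str = "test.tsv",
    sequence_file: str = "sequences.fasta",
    sep: str = "\t",
    on_duplicate: str = "error",
) -> GoldStandard:
    """Load a pre-partitioned gold-standard distribution.

    Verifies protein-disjointness across the three partitions and issues a
    warning (not an error) listing shared proteins if any overlap is found.
    Missing files raise :class:`FileNotFoundError`.
    """
    directory = Path(directory)
    paths = {
        "train": directory / train_file,
        "validation": directory / validation_file,
        "test": directory / test_file,
    }
    for name, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"gold-standard {name} file not found: {p}")
    seq_path = directory / sequence_file
    if not seq_path.exists():
        raise FileNotFoundError(f"gold-standard sequence file not found: {seq_path}")

    datasets = {
        name: read_interactions(p, sep=sep, on_duplicate=on_duplicate)
        for name, p in paths.items()
    }
    sequences = read_fasta(seq_path)

    overlaps: dict[str, frozenset[str]] = {}
    names = list(datasets)
    for i, x in enumerate(names):
        for y in names[i + 1 :]:
            shared = frozenset(datasets[x].proteins & datasets[y].proteins)
            overlaps[f"{x}/{y}"] = shared
            if shared:
                sample = ", ".join(sorted(shared)[:10])
                warnings.warn(
                    f"gold standard: {len(shared)} protein(s) shared between "
                    f"{x} and {y} partitions (e.g. {sample})",
                    stacklevel=2,
                )
    return GoldStandard(
        train=datasets["train"],
        validation=datasets["validation"],
        test=datasets["test"],
        sequences=sequences,
        overlaps=overlaps,
    )
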