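"""Read, validate, and summarize multi-label protein location datasets.

A dataset is a FASTA file of protein sequences plus a tab-separated label
table mapping each protein id to a comma-separated list of location names
(``P12345<TAB>Nucleus,Cytoplasm``).  Every protein must carry at least one
location: the ranking metrics divide by the number of positive labels per
protein, so unlocated records are rejected at load time rather than
propagated.

The summary statistics mirror the way multi-label localization benchmarks
are usually described: per-location counts, the total number of (protein,
location) assignments, the positive-case rate over the n x L label matrix,
the label-multiplicity histogram (how many proteins sit in exactly m
compartments), and the location co-occurrence matrix.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from sublocnet.errors import ValidationError

__all__ = [
    "LocationVocabulary",
    "ProteinRecord",
    "AnnotatedProteinSet",
    "DatasetStats",
    "load_dataset",
    "write_dataset",
    "dataset_statistics",
    "counts_summary",
    "multilocation_summary",
    "multiplicity_fractions",
    "cross_validation_folds",
]


@dataclass(frozen=True)
class LocationVocabulary:
    """Ordered list of location names; order defines the label-column index."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValidationError(f"vocabulary needs >= 2 locations, got {len(self.names)}")
        if len(set(self.names)) != len(self.names):
            dup = [n for n, c in Counter(self.names).items() if c > 1]
            raise ValidationError(f"duplicated location names: {dup}")
        if any(not n for n in self.names):
            raise ValidationError("empty location name in vocabulary")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"unknown location name: {name!r}") from None

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "LocationVocabulary":
        """Infer order: descending count, ties broken by name."""
        ordered = sorted(counts, key=lambda n: (-counts[n], n))
        return cls(tuple(ordered))


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    labels: np.ndarray  # binary vector, length L

    def label_names(self, vocabulary: LocationVocabulary) -> list[str]:
        return [vocabulary.names[j] for j in np.flatnonzero(self.labels)]


@dataclass
class AnnotatedProteinSet:
    """Proteins with sequences and binary multi-label location annotations."""

    vocabulary: LocationVocabulary
    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        L = len(self.vocabulary)
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValidationError(f"duplicated protein id: {rec.id!r}")
            seen.add(rec.id)
            if not rec.sequence:
                raise ValidationError(f"protein {rec.id!r} has an empty sequence")
            if len(rec.labels) != L:
                raise ValidationError(
                    f"protein {rec.id!r}: label vector length {len(rec.labels)} != vocabulary size {L}"
                )
            if int(np.sum(rec.labels)) < 1:
                raise ValidationError(f"protein {rec.id!r} has zero location labels")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def label_matrix(self) -> np.ndarray:
        """n x L binary matrix in record order."""
        return np.array([r.labels for r in self.records], dtype=np.int64)

    def subset(self, ids: Iterable[str]) -> "AnnotatedProteinSet":
        wanted = set(ids)
        recs = [r for r in self.records if r.id in wanted]
        missing = wanted - {r.id for r in recs}
        if missing:
            raise ValidationError(f"ids not in dataset: {sorted(missing)}")
        return AnnotatedProteinSet(self.vocabulary, recs)


@dataclass
class DatasetStats:
    """Table-style summary of a multi-label protein dataset."""

    per_location_counts: dict[str, int]
    total_assignments: int
    n_proteins: int
    n_locations: int
    positive_rate: float
    per_location_fraction: dict[str, float]
    multiplicity_histogram: dict[int, int]
    cooccurrence: np.ndarray = field(repr=False)

    def to_json(self) -> str:
        payload = {
            "per_location_counts": self.per_location_counts,
            "total_assignments": self.total_assignments,
            "n_proteins": self.n_proteins,
            "n_locations": self.n_locations,
            "positive_rate": self.positive_rate,
            "per_location_fraction": self.per_location_fraction,
            "multiplicity_histogram": {str(m): c for m, c in self.multiplicity_histogram.items()},
            "cooccurrence": self.cooccurrence.tolist(),
        }
        return json.dumps(payload, indent=2)

    def to_table(self) -> str:
        """Text table: one row per location plus a total row."""
        width = max(len(n) for n in self.per_location_counts) + 2
        lines = [f"{'Subcellular location':<{width}}{'Count':>8}{'Fraction':>10}"]
        for name, count in self.per_location_counts.items():
            frac = self.per_location_fraction[name]
            lines.append(f"{name:<{width}}{count:>8}{frac:>10.1%}")
        lines.append(f"{'Total':<{width}}{self.total_assignments:>8}")
        lines.append(
            f"Positive cases: {self.total_assignments} of "
            f"{self.n_proteins} x {self.n_locations} = {self.positive_rate:.2%}"
        )
        return "\n".join(lines)


def _read_label_table(labels_path: Path) -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    text = Path(labels_path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(
                f"{labels_path}:{lineno}: expected 'id<TAB>Loc1,Loc2,...', got {line!r}"
            )
        pid, locs = parts[0].strip(), parts[1]
        if pid in table:
            raise ValidationError(f"{labels_path}:{lineno}: duplicated protein id {pid!r}")
        names = [s.strip() for s in locs.split(",") if s.strip()]
        if not names:
            raise ValidationError(f"{labels_path}:{lineno}: protein {pid!r} has zero labels")
        table[pid] = names
    if not table:
        raise ValidationError(f"{labels_path}: no label rows found")
    return table


def load_dataset(
    fasta_path: str | Path,
    labels_path: str | Path,
    vocabulary: LocationVocabulary | None = None,
) -> AnnotatedProteinSet:
    """Load FASTA sequences plus the id -> location-list label table.

    Ids must correspond one-to-one between the two files; a protein present in
    only one of them is an error.  When ``vocabulary`` is None it is inferred
    from the label table (descending count, ties by name).
    """
    labels = _read_label_table(Path(labels_path))
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"{fasta_path}: duplicated protein id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()

    only_fasta = sorted(set(seqs) - set(labels))
    only_labels = sorted(set(labels) - set(seqs))
    if only_fasta or only_labels:
        raise ValidationError(
            f"id mismatch between {fasta_path} and {labels_path}: "
            f"FASTA-only {only_fasta[:5]}, labels-only {only_labels[:5]}"
        )

    if vocabulary is None:
        counts = Counter(name for names in labels.values() for name in names)
        vocabulary = LocationVocabulary.from_counts(counts)

    L = len(vocabulary)
    records = []
    for pid in seqs:  # FASTA order
        vec = np.zeros(L, dtype=np.int64)
        for name in labels[pid]:
            vec[vocabulary.index(name)] = 1
        records.append(ProteinRecord(pid, seqs[pid], vec))
    return AnnotatedProteinSet(vocabulary, records)


def write_dataset(
    data: AnnotatedProteinSet, fasta_path: str | Path, labels_path: str | Path
) -> None:
    """Write a dataset back to FASTA + labels TSV (round-trips with load_dataset)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in data.records
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    lines = [
        f"{r.id}\t{','.join(r.label_names(data.vocabulary))}" for r in data.records
    ]
    Path(labels_path).write_text("\n".join(lines) + "\n")


def counts_summary(
    per_location_counts: Mapping[str, int] | Sequence[int], n_proteins: int
) -> tuple[int, float, dict[str, float] | list[float]]:
    """Totals from per-location counts alone (no sequences needed).

    Returns ``(total_assignments, positive_rate, per_location_fraction)`` where
    positive_rate = total / (n_proteins * L) and each fraction is
    count / n_proteins.  Accepts either a name->count mapping or a plain count
    sequence.
    """
    if n_proteins < 1:
        raise ValidationError("n_proteins must be >= 1")
    if isinstance(per_location_counts, Mapping):
        values = list(per_location_counts.values())
    else:
        values = list(per_location_counts)
    if len(values) < 2:
        raise ValidationError("need counts for >= 2 locations")
    total = int(sum(values))
    rate = total / (n_proteins * len(values))
    if isinstance(per_location_counts, Mapping):
        frac: dict[str, float] | list[float] = {
            name: c / n_proteins for name, c in per_location_counts.items()
        }
    else:
        frac = [c / n_proteins for c in values]
    return total, rate, frac


def dataset_statistics(data: AnnotatedProteinSet) -> DatasetStats:
    """Compute all summary statistics of an annotated set."""
    if len(data) == 0:
        raise ValidationError("empty dataset")
    Y = data.label_matrix()
    n, L = Y.shape
    col_counts = Y.sum(axis=0)
    per_location = {
        name: int(c) for name, c in zip(data.vocabulary.names, col_counts)
    }
    total = int(col_counts.sum())
    row_sums = Y.sum(axis=1)
    hist = {int(m): int(c) for m, c in sorted(Counter(row_sums.tolist()).items())}
    cooc = Y.T @ Y
    return DatasetStats(
        per_location_counts=per_location,
        total_assignments=total,
        n_proteins=n,
        n_locations=L,
        positive_rate=total / (n * L),
        per_location_fraction={name: c / n for name, c in per_location.items()},
        multiplicity_histogram=hist,
        cooccurrence=cooc,
    )


def multiplicity_fractions(
    histogram: Mapping[int, int],
) -> dict[int, float] | None:
    """Fractions of multi-location proteins by multiplicity m >= 2.

    fraction[m] = count[m] / (number of proteins with >= 2 locations).  Returns
    None when the set contains no multi-location protein (the fractions are
    undefined, not zero).
    """
    multi = {int(m): int(c) for m, c in histogram.items() if int(m) >= 2 and c > 0}
    denom = sum(multi.values())
    if denom == 0:
        return None
    return {m: c / denom for m, c in sorted(multi.items())}


def multilocation_summary(
    data: AnnotatedProteinSet,
) -> dict[int, dict[str, float | int | None]]:
    """Per-multiplicity counts and, for m >= 2, the fraction among multi-location proteins."""
    if len(data) == 0:
        raise ValidationError("empty dataset")
    stats = dataset_statistics(data)
    fractions = multiplicity_fractions(stats.multiplicity_histogram)
    out: dict[int, dict[str, float | int | None]] = {}
    for m, c in stats.multiplicity_histogram.items():
        frac = None
        if m >= 2 and fractions is not None:
            frac = fractions.get(m)
        out[m] = {"count": c, "fraction": frac}
    return out


def cross_validation_folds(
    data: AnnotatedProteinSet, k: int, seed: int, stratify: bool = False
) -> list[tuple[list[str], list[str]]]:
    """Partition protein ids into k folds: list of (train_ids, test_ids).

    Plain uniform shuffle by default; ``stratify=True`` greedily balances the
    rarest positive label of each protein across folds.  Deterministic for a
    fixed seed; test sets partition the ids with sizes differing by <= 1.
    """
    n = len(data)
    if not 2 <= k <= n:
        raise ValidationError(f"k must be in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    ids = sorted(data.ids)
    order = rng.permutation(n)

    fold_of: dict[str, int] = {}
    if stratify:
        # rarest-label-first greedy assignment, cycling folds within each group
        Y = data.label_matrix()
        col_counts = Y.sum(axis=0)
        by_id = {r.id: r.labels for r in data.records}
        def rarest(pid: str) -> int:
            pos = np.flatnonzero(by_id[pid])
            return int(pos[np.argmin(col_counts[pos])])
        shuffled = [ids[i] for i in order]
        groups: dict[int, list[str]] = {}
        for pid in shuffled:
            groups.setdefault(rarest(pid), []).append(pid)
        counter = 0
        for lab in sorted(groups):
            for pid in groups[lab]:
                fold_of[pid] = counter % k
                counter += 1
    else:
        for pos, i in enumerate(order):
            fold_of[ids[i]] = pos % k

    folds = []
    for f in range(k):
        test = [pid for pid in data.ids if fold_of[pid] == f]
        train = [pid for pid in data.ids if fold_of[pid] != f]
        folds.append((train, test))
    return folds
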