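"""Synthetic multi-label protein benchmarks with planted location motifs.

Each location owns a distinct short motif (pairwise Hamming distance >= 2).
A protein drawn from the generator gets 1-4 locations (heavily skewed toward
single-location proteins, mirroring how curated localization benchmarks are
composed), and for every positive location a fixed number of motif copies is
inserted at non-overlapping uniform positions into an otherwise uniform-
random sequence.  The signal is therefore decodable both from the raw
sequence (BLSTM branch) and from the pseudo-PSSM (conserved own-residue
columns at every position, including motif sites).

The pseudo-PSSM emulates the *shape* of PSI-BLAST profiles, not real
evolution: the 20 log-odds columns are background noise around -1 with the
residue's own column raised by a conservation bonus; the 20 percentage
columns are the softmax of the log-odds row rescaled to sum to 100; the
final two columns carry an information-content value and a constant relative
weight.  Matrices are deterministic given (seed, sequence).
"""

from __future__ import annotations

import json
import zlib
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from sublocnet.datasets import (
    AnnotatedProteinSet,
    LocationVocabulary,
    ProteinRecord,
    write_dataset,
)
from sublocnet.encoding import PSIBLAST_RESIDUE_ORDER, write_matrix_tsv
from sublocnet.errors import ValidationError

__all__ = [
    "SyntheticConfig",
    "PseudoPSSMStore",
    "generate_dataset",
    "generate_pseudo_pssm",
    "write_run",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Compartment names reused for the default 14-location benchmark.
DEFAULT_LOCATION_NAMES = (
    "Nucleus", "Cytoplasm", "Extracellular", "Mitochondrion", "Plasma membrane",
    "Endoplasmic reticulum", "Golgi apparatus", "Cytoskeleton", "Centriole",
    "Lysosome", "Peroxisome", "Endosome", "Microsome", "Synapse",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults define the package's standard benchmark."""

    n_proteins: int = 1000
    n_locations: int = 14
    motif_length: int = 6
    motifs_per_positive: int = 2
    length_mean: float = 300.0
    length_sd: float = 60.0
    min_length: int = 50
    multiplicity_weights: tuple[float, ...] = (0.83, 0.15, 0.017, 0.003)
    location_weights: tuple[float, ...] | None = None
    pssm_conservation: float = 5.0
    pssm_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        if self.n_locations < 2:
            raise ValidationError("n_locations must be >= 2")
        if self.motif_length < 3:
            raise ValidationError("motif_length must be >= 3")
        if self.length_sd <= 0:
            raise ValidationError("length_sd must be > 0")
        if abs(sum(self.multiplicity_weights) - 1.0) > 1e-9:
            raise ValidationError("multiplicity_weights must sum to 1")
        if len(self.multiplicity_weights) > self.n_locations:
            raise ValidationError("more multiplicity classes than locations")
        if self.location_weights is not None and len(self.location_weights) != self.n_locations:
            raise ValidationError("location_weights length must equal n_locations")


def _location_names(n: int) -> tuple[str, ...]:
    if n <= len(DEFAULT_LOCATION_NAMES):
        return DEFAULT_LOCATION_NAMES[:n]
    extra = tuple(f"Location{i:02d}" for i in range(len(DEFAULT_LOCATION_NAMES) + 1, n + 1))
    return DEFAULT_LOCATION_NAMES + extra


def _draw_motifs(rng: np.random.Generator, config: SyntheticConfig) -> list[str]:
    """Distinct motifs, pairwise Hamming distance >= 2."""
    motifs: list[np.ndarray] = []
    attempts = 0
    while len(motifs) < config.n_locations:
        cand = rng.integers(0, len(STANDARD_AA), size=config.motif_length)
        if all(int(np.sum(cand != m)) >= 2 for m in motifs):
            motifs.append(cand)
        attempts += 1
        if attempts > 1000 * config.n_locations:
            raise ValidationError(
                "could not draw pairwise-distant motifs; motif_length too small "
                "for the requested number of locations"
            )
    return ["".join(STANDARD_AA[i] for i in m) for m in motifs]


def _place_non_overlapping(
    rng: np.random.Generator, length: int, motif_len: int, n_slots: int
) -> list[int]:
    """Uniform non-overlapping start positions by rejection sampling."""
    taken: list[tuple[int, int]] = []
    starts: list[int] = []
    for _ in range(n_slots):
        for _attempt in range(200):
            s = int(rng.integers(0, length - motif_len + 1))
            if all(s + motif_len <= a or s >= b for a, b in taken):
                taken.append((s, s + motif_len))
                starts.append(s)
                break
        else:
            raise ValidationError(
                f"could not place {n_slots} non-overlapping motifs of length "
                f"{motif_len} in a sequence of length {length}"
            )
    return starts


def generate_pseudo_pssm(sequence: str, config: SyntheticConfig) -> np.ndarray:
    """Conservation-structured raw pseudo-PSSM (n x 42), deterministic per (seed, sequence)."""
    if not sequence:
        raise ValidationError("empty sequence")
    n = len(sequence)
    rng = np.random.default_rng([config.seed, zlib.crc32(sequence.encode())])
    logodds = rng.normal(-1.0, config.pssm_noise_sd, size=(n, 20)) if config.pssm_noise_sd > 0 \
        else np.full((n, 20), -1.0)
    col_of = {aa: j for j, aa in enumerate(PSIBLAST_RESIDUE_ORDER)}
    own = np.array([col_of.get(a, -1) for a in sequence])
    valid = own >= 0
    logodds[np.flatnonzero(valid), own[valid]] += config.pssm_conservation
    # percentage block: softmax of the log-odds row, rescaled to sum to 100
    z = logodds - logodds.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    percentages = 100.0 * p
    # information content in bits against a uniform background of 1/20
    with np.errstate(divide="ignore", invalid="ignore"):
        info = np.sum(np.where(p > 0, p * np.log2(p * 20.0), 0.0), axis=1)
    weight = np.ones(n)
    return np.hstack([logodds, percentages, info[:, None], weight[:, None]])


class PseudoPSSMStore(Mapping):
    """Lazy id -> raw pseudo-PSSM mapping; matrices are generated on first access."""

    def __init__(self, sequences: dict[str, str], config: SyntheticConfig):
        self._sequences = sequences
        self._config = config
        self._cache: dict[str, np.ndarray] = {}

    def __getitem__(self, key: str) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = generate_pseudo_pssm(self._sequences[key], self._config)
        return self._cache[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sequences)

    def __len__(self) -> int:
        return len(self._sequences)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[AnnotatedProteinSet, PseudoPSSMStore, dict]:
    """Generate (annotated set, pseudo-PSSM store, ground-truth motif table)."""
    rng = np.random.default_rng(config.seed)
    names = _location_names(config.n_locations)
    vocabulary = LocationVocabulary(names)
    motifs = _draw_motifs(rng, config)
    mult_values = np.arange(1, len(config.multiplicity_weights) + 1)
    loc_w = None
    if config.location_weights is not None:
        loc_w = np.asarray(config.location_weights, dtype=np.float64)
        loc_w = loc_w / loc_w.sum()

    records: list[ProteinRecord] = []
    positions: dict[str, dict[str, list[int]]] = {}
    aa_idx = np.arange(len(STANDARD_AA))
    for i in range(config.n_proteins):
        pid = f"SYN{i + 1:05d}"
        length = max(config.min_length, int(round(rng.normal(config.length_mean, config.length_sd))))
        m = int(rng.choice(mult_values, p=np.asarray(config.multiplicity_weights)))
        locs = rng.choice(config.n_locations, size=m, replace=False, p=loc_w)
        capacity = m * config.motifs_per_positive * config.motif_length
        if capacity > length:
            raise ValidationError(
                f"protein {pid}: {capacity} motif residues exceed sequence length {length}"
            )
        seq = rng.choice(aa_idx, size=length)
        starts = _place_non_overlapping(
            rng, length, config.motif_length, m * config.motifs_per_positive
        )
        labels = np.zeros(config.n_locations, dtype=np.int64)
        pos_table: dict[str, list[int]] = {}
        slot = 0
        for loc in locs:
            labels[loc] = 1
            motif = motifs[loc]
            loc_starts = []
            for _ in range(config.motifs_per_positive):
                s = starts[slot]; slot += 1
                for k, aa in enumerate(motif):
                    seq[s + k] = STANDARD_AA.index(aa)
                loc_starts.append(s)
            pos_table[names[loc]] = sorted(loc_starts)
        sequence = "".join(STANDARD_AA[j] for j in seq)
        records.append(ProteinRecord(pid, sequence, labels))
        positions[pid] = pos_table

    data = AnnotatedProteinSet(vocabulary, records)
    store = PseudoPSSMStore({r.id: r.sequence for r in records}, config)
    truth = {
        "motifs": {names[j]: motifs[j] for j in range(config.n_locations)},
        "positions": positions,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
    }
    return data, store, truth


def write_run(
    data: AnnotatedProteinSet,
    store: PseudoPSSMStore,
    truth: dict,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write FASTA + labels TSV + per-protein PSSM TSVs + ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "proteins.fasta"
    labels = out / "labels.tsv"
    write_dataset(data, fasta, labels)
    pssm_dir = out / "pssms"
    pssm_dir.mkdir(exist_ok=True)
    for pid in store:
        write_matrix_tsv(store[pid], pssm_dir / f"{pid}.tsv")
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return {"fasta": fasta, "labels": labels, "pssm_dir": pssm_dir, "truth": truth_path}
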