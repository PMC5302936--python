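"""Seeded synthetic inputs with known ground truth for every pipeline stage.

Three generators, all pure functions of their spec (seed included):

* proteomes — i.i.d. background residues from a chosen frequency table, with
  motif-carrying peptides planted at recorded, non-overlapping locations
  (insertions overwrite background residues so window counts stay
  analytically computable);
* exchange-scan ELISpot tables — replicate spot counts drawn around
  per-variant means determined by the planted truth (abolished / partial /
  unaffected shrink the background-subtracted original response to 5% / 50% /
  95% by default, well clear of the 0.25 / 0.75 call thresholds);
* toy PSSMs — a small random integer baseline plus a bonus on each
  (position, residue) cell of a favored peptide.

The study-scale defaults mirror a triplicate nonamer ELISpot screen
(original ~100 spots over ~5 background, the scan pulsed at 0.01 μM).
Randomness comes from a single ``numpy.random.default_rng`` per call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .exchange_scan import Call, ExchangeScanTable, Peptide, VariantRow
from .mhc_pssm import PSSMMatrix
from .motif_engine import AMINO_ACIDS, ProteinRecord, _AA_SET

UNIFORM_FREQUENCIES: dict[str, float] = {aa: 1.0 / 20.0 for aa in AMINO_ACIDS}

# default effect sizes: fraction of background-subtracted original response
DEFAULT_EFFECTS: dict[Call, float] = {
    "abolished": 0.05,
    "partial": 0.5,
    "unaffected": 0.95,
}


class CapacityError(ValueError):
    """Planted copies cannot be placed without overlap at the requested size."""


# ---------------------------------------------------------------------------
# Proteomes with planted motif occurrences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteomeSpec:
    n_proteins: int
    length_range: tuple[int, int]  # uniform inclusive range
    residue_frequencies: Mapping[str, float]
    planted: tuple[tuple[str, int], ...]  # (peptide, copies)
    seed: int

    def __post_init__(self):
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad length range {self.length_range}")
        total = sum(self.residue_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"residue frequencies sum to {total}, not 1")
        for res in self.residue_frequencies:
            if res not in _AA_SET:
                raise ValueError(f"non-standard residue {res!r} in frequencies")
        for pep, copies in self.planted:
            if copies < 0:
                raise ValueError("planted copy count must be >= 0")
            if any(r not in _AA_SET for r in pep):
                raise ValueError(f"non-standard residue in planted peptide {pep!r}")


def generate_proteome(
    spec: ProteomeSpec,
) -> tuple[list[ProteinRecord], dict]:
    """Generate FASTA records plus a ground-truth manifest.

    Background residues are drawn i.i.d. from ``residue_frequencies``; each
    planted copy overwrites a window chosen uniformly among positions that do
    not overlap a previously planted window. The manifest records every
    planted location as ``{"peptide", "protein_id", "offset"}`` (0-based).
    Identical specs (seed included) give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    residues = sorted(spec.residue_frequencies)
    probs = np.array([spec.residue_frequencies[r] for r in residues])
    probs = probs / probs.sum()
    lo, hi = spec.length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_proteins)
    seqs = [
        list(rng.choice(list(residues), size=length, p=probs))
        for length in lengths
    ]
    occupied: list[list[tuple[int, int]]] = [[] for _ in seqs]  # half-open spans
    locations: list[dict] = []
    for pep, copies in spec.planted:
        L = len(pep)
        for _ in range(copies):
            candidates = []
            for pi, seq in enumerate(seqs):
                for off in range(len(seq) - L + 1):
                    if all(
                        off + L <= s or off >= e for s, e in occupied[pi]
                    ):
                        candidates.append((pi, off))
            if not candidates:
                raise CapacityError(
                    f"cannot place planted peptide {pep!r} without overlap"
                )
            pi, off = candidates[rng.integers(len(candidates))]
            seqs[pi][off : off + L] = list(pep)
            occupied[pi].append((off, off + L))
            locations.append(
                {"peptide": pep, "protein_id": f"synth|{pi + 1}", "offset": off}
            )
    records = [
        ProteinRecord(identifier=f"synth|{i + 1}", sequence="".join(seq))
        for i, seq in enumerate(seqs)
    ]
    manifest = {
        "seed": spec.seed,
        "n_proteins": spec.n_proteins,
        "length_range": list(spec.length_range),
        "planted": locations,
        "planted_unique_peptides": sorted({p for p, c in spec.planted if c > 0}),
        "total_residues": int(sum(lengths)),
    }
    return records, manifest


# ---------------------------------------------------------------------------
# Exchange-scan tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanSpec:
    original: Peptide
    true_calls: Mapping[int, tuple[Call, str]]  # position -> (call, substituted)
    mean_spots_original: float = 100.0
    mean_background: float = 5.0
    noise_model: Literal["poisson", "negative_binomial", "exact"] = "poisson"
    dispersion: float = 10.0  # negative-binomial size parameter
    replicates: int = 3
    seed: int = 0
    effects: Mapping[Call, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )

    def __post_init__(self):
        if not self.mean_spots_original > self.mean_background >= 0:
            raise ValueError("need mean_spots_original > mean_background >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for pos, (call, sub) in self.true_calls.items():
            if not (1 <= pos <= len(self.original)):
                raise ValueError(f"true call position {pos} outside peptide")
            if call not in ("abolished", "partial", "unaffected"):
                raise ValueError(f"unknown call {call!r}")
            if sub == self.original.sequence[pos - 1]:
                raise ValueError(f"substitution at {pos} equals original residue")


def default_substitution(original_residue: str) -> str:
    """Alanine scan convention: substitute A, or S where the original is A."""
    return "S" if original_residue == "A" else "A"


def _draw_counts(rng: np.random.Generator, mean: float, spec: ScanSpec) -> tuple[int, ...]:
    if spec.noise_model == "exact":
        return tuple(int(round(mean)) for _ in range(spec.replicates))
    if spec.noise_model == "poisson":
        return tuple(int(c) for c in rng.poisson(mean, size=spec.replicates))
    # negative binomial with mean `mean` and size (dispersion) r: p = r/(r+mean)
    r = spec.dispersion
    p = r / (r + mean) if mean > 0 else 1.0
    return tuple(int(c) for c in rng.negative_binomial(r, p, size=spec.replicates))


def generate_scan_table(spec: ScanSpec) -> ExchangeScanTable:
    """Simulate a full single-substitution scan of the original peptide.

    Every position gets exactly one variant row: the substitution and truth
    category from ``true_calls`` where given, otherwise the default
    alanine-scan substitution with an ``unaffected`` truth. Per-variant mean
    = background + effect * (original - background); replicates are drawn
    from the noise model around the means (the original and background rows
    included).
    """
    rng = np.random.default_rng(spec.seed)
    delta = spec.mean_spots_original - spec.mean_background
    original_counts = _draw_counts(rng, spec.mean_spots_original, spec)
    background_counts = _draw_counts(rng, spec.mean_background, spec)
    variants = []
    for pos in range(1, len(spec.original) + 1):
        if pos in spec.true_calls:
            call, sub = spec.true_calls[pos]
        else:
            call, sub = "unaffected", default_substitution(
                spec.original.sequence[pos - 1]
            )
        mean = spec.mean_background + spec.effects[call] * delta
        variants.append(VariantRow(pos, sub, _draw_counts(rng, mean, spec)))
    return ExchangeScanTable(
        original=spec.original,
        variants=tuple(variants),
        original_counts=original_counts,
        background_counts=background_counts,
        pulse_concentration_uM=0.01,
    )


# ---------------------------------------------------------------------------
# Toy PSSMs
# ---------------------------------------------------------------------------


def generate_pssm(
    length: int,
    favored: Peptide,
    bonus: int,
    seed: int,
    baseline_max: int = 3,
    allele: str = "SYNTH",
) -> PSSMMatrix:
    """Toy matrix: random baseline in [0, baseline_max] plus ``bonus`` on the
    favored peptide's own (position, residue) cells.

    The favored peptide then scores maximally among same-composition
    permutations. Deterministic for a fixed seed.
    """
    if len(favored) != length:
        raise ValueError("favored peptide length must equal matrix length")
    if bonus <= 0:
        raise ValueError("bonus must be > 0")
    rng = np.random.default_rng(seed)
    scores: dict[tuple[int, str], int] = {}
    for pos in range(1, length + 1):
        for res in AMINO_ACIDS:
            scores[(pos, res)] = int(rng.integers(0, baseline_max + 1))
    for pos, res in enumerate(favored.sequence, start=1):
        scores[(pos, res)] += bonus
    return PSSMMatrix(allele=allele, length=length, scores=scores)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
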