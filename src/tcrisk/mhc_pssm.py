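"""Additive MHC class I binding scoring with position-specific scoring matrices.

SYFPEITHI-style prediction: a peptide's binding score for an HLA allele is
the sum, over peptide positions, of an integer score for the residue seen at
that position. Anchor residues (positions 2 and 9 for HLA-A*02:01 nonamers)
carry the largest entries; residues absent from a sparse published table
contribute a configurable default (0). No affinity (nM) or percentile-rank
conversion is performed — the raw additive score is the comparison unit.

Matrix file format (TSV): optional ``#`` comment lines (``# allele: ...``
carries the allele label), a header row ``position<TAB>residue...`` with
single-letter residue columns, then one row per position labelled ``P1..PL``
with integer cells.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .motif_engine import AMINO_ACIDS, _AA_SET


class MatrixFormatError(ValueError):
    """Raised for structural problems in a matrix file, naming the location."""


@dataclass(frozen=True)
class PSSMMatrix:
    """Per-(position, residue) integer score table for one HLA allele.

    ``scores`` maps ``(position, residue)`` with 1-based positions to integer
    scores; pairs absent from the mapping score ``default_score``.
    """

    allele: str
    length: int
    scores: dict[tuple[int, str], int]
    default_score: int = 0

    def __post_init__(self):
        if self.length < 8:
            raise ValueError(f"matrix length {self.length} < 8")
        for (pos, res) in self.scores:
            if not (1 <= pos <= self.length):
                raise ValueError(f"score position {pos} outside 1..{self.length}")
            if res not in _AA_SET:
                raise ValueError(f"non-standard residue {res!r} in matrix")

    def entry(self, position: int, residue: str) -> int:
        return self.scores.get((position, residue), self.default_score)

    def max_score(self) -> int:
        """Largest achievable peptide score (used to normalize risk indices)."""
        total = 0
        for pos in range(1, self.length + 1):
            col = [self.entry(pos, r) for r in AMINO_ACIDS]
            total += max(col)
        return total

    def __add__(self, other: "PSSMMatrix") -> "PSSMMatrix":
        """Entrywise sum; requires equal lengths. Allele labels concatenate."""
        if self.length != other.length:
            raise ValueError("cannot add matrices of different lengths")
        keys = set(self.scores) | set(other.scores)
        summed = {
            k: self.scores.get(k, self.default_score)
            + other.scores.get(k, other.default_score)
            for k in keys
        }
        return PSSMMatrix(
            allele=f"{self.allele}+{other.allele}",
            length=self.length,
            scores=summed,
            default_score=self.default_score + other.default_score,
        )


@dataclass(frozen=True, order=True)
class ScoredPeptide:
    peptide: str
    score: int
    allele: str


_POSITION_RE = re.compile(r"^P(\d+)$", re.IGNORECASE)


def load_matrix(path, allow_float: bool = False) -> PSSMMatrix:
    """Load a matrix TSV (format in the module docstring).

    Integer cells are required by default (SYFPEITHI convention);
    ``allow_float`` accepts real-valued matrices, truncating nothing — scores
    are then floats and the matrix is non-canonical.
    """
    allele = "unknown"
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*allele\s*:\s*(\S.*)$", line, re.IGNORECASE)
                if m:
                    allele = m.group(1).strip()
                continue
            cells = line.split("\t")
            if header is None:
                if cells[0].strip().lower() != "position":
                    raise MatrixFormatError(
                        f"line {lineno}: header must start with 'position'"
                    )
                header = [c.strip().upper() for c in cells[1:]]
                for col in header:
                    if col not in _AA_SET:
                        raise MatrixFormatError(
                            f"line {lineno}: unknown residue column {col!r}"
                        )
                if len(set(header)) != len(header):
                    raise MatrixFormatError(f"line {lineno}: duplicate residue column")
                continue
            m = _POSITION_RE.match(cells[0].strip())
            if not m:
                raise MatrixFormatError(
                    f"line {lineno}: position label {cells[0]!r} not of form P<k>"
                )
            rows.append((int(m.group(1)), [c.strip() for c in cells[1:]]))
    if header is None:
        raise MatrixFormatError("missing header row")
    if not rows:
        raise MatrixFormatError("no position rows")
    positions = [p for p, _ in rows]
    dupes = {p for p in positions if positions.count(p) > 1}
    if dupes:
        raise MatrixFormatError(f"duplicated position rows: P{sorted(dupes)[0]}")
    length = max(positions)
    if sorted(positions) != list(range(1, length + 1)):
        raise MatrixFormatError("position rows must cover P1..PL without gaps")
    scores: dict[tuple[int, str], int] = {}
    for pos, cells in rows:
        if len(cells) != len(header):
            raise MatrixFormatError(f"row P{pos}: expected {len(header)} cells")
        for res, cell in zip(header, cells):
            if cell == "":
                continue  # blank cell = unlisted pair, scores default
            try:
                value = int(cell)
            except ValueError:
                if allow_float:
                    value = float(cell)
                else:
                    raise MatrixFormatError(
                        f"row P{pos}, residue {res}: non-integer cell {cell!r}"
                    ) from None
            scores[(pos, res)] = value
    return PSSMMatrix(allele=allele, length=length, scores=scores)


def save_matrix(matrix: PSSMMatrix, path) -> None:
    """Write the matrix in the TSV format :func:`load_matrix` reads.

    All 20 residue columns are emitted; pairs absent from ``matrix.scores``
    are written as blank cells so the sparse structure round-trips.
    """
    with open(path, "w") as fh:
        fh.write(f"# allele: {matrix.allele}\n")
        fh.write(f"# default_score: {matrix.default_score}\n")
        fh.write("position\t" + "\t".join(AMINO_ACIDS) + "\n")
        for pos in range(1, matrix.length + 1):
            cells = [
                str(matrix.scores[(pos, r)]) if (pos, r) in matrix.scores else ""
                for r in AMINO_ACIDS
            ]
            fh.write(f"P{pos}\t" + "\t".join(cells) + "\n")


def score_peptide(matrix: PSSMMatrix, peptide: str) -> ScoredPeptide:
    """Additive score: sum of per-position entries with the default fallback."""
    peptide = peptide.upper()
    if len(peptide) != matrix.length:
        raise ValueError(
            f"peptide length {len(peptide)} != matrix length {matrix.length}"
        )
    bad = [r for r in peptide if r not in _AA_SET]
    if bad:
        raise ValueError(f"non-standard residue {bad[0]!r} in peptide {peptide!r}")
    total = sum(matrix.entry(pos, res) for pos, res in enumerate(peptide, start=1))
    return ScoredPeptide(peptide=peptide, score=total, allele=matrix.allele)


def score_set(
    matrix: PSSMMatrix,
    peptides,
    min_score: int | None = None,
) -> list[ScoredPeptide]:
    """Score a peptide collection; filter to ``score >= min_score`` if given.

    Output is sorted by descending score, ties broken lexicographically by
    peptide. Contract errors from :func:`score_peptide` propagate naming the
    offending peptide.
    """
    scored = []
    for pep in peptides:
        try:
            scored.append(score_peptide(matrix, pep))
        except ValueError as exc:
            raise ValueError(f"peptide {pep!r}: {exc}") from exc
    if min_score is not None:
        scored = [s for s in scored if s.score >= min_score]
    scored.sort(key=lambda s: (-s.score, s.peptide))
    return scored


def write_scores_tsv(scored: list[ScoredPeptide], path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tallele\tscore\n")
        for s in scored:
            fh.write(f"{s.peptide}\t{s.allele}\t{s.score}\n")
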