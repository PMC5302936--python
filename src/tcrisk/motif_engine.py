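"""PROSITE-style motif parsing and proteome window scanning.

A TCR recognition motif derived from an amino-acid exchange scan is a
fixed-length, per-position pattern: crucial positions are fixed to the
original residue, tolerated positions are wildcards (``X``), and partially
tolerated positions are small bracketed residue classes such as ``[LA]``.
This module parses that dialect, matches it against fixed-length peptide
windows, and enumerates every matching window in a protein FASTA database —
the local equivalent of running the pattern through ScanProsite.

Dialect restriction: hyphen-separated elements that are either ``X``/``x``
(any residue), a single residue letter, ``[..]`` (allowed set) or ``{..}``
(excluded set). Repetition counts and N/C-terminal anchors are not part of
the dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

NonstandardPolicy = Literal["skip", "wildcard-fail", "error"]


class PatternParseError(ValueError):
    """Raised when a motif string does not conform to the dialect."""

    def __init__(self, message: str, element_index: int | None = None):
        self.element_index = element_index
        if element_index is not None:
            message = f"element {element_index}: {message}"
        super().__init__(message)


class NonstandardResidueError(ValueError):
    """Raised under the ``error`` policy when a window holds a non-standard residue."""


# ---------------------------------------------------------------------------
# Residue classes and patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidueClass:
    """One motif position: wildcard, fixed residue, inclusion or exclusion set.

    ``kind`` is one of ``wildcard``, ``fixed``, ``include``, ``exclude``;
    ``residues`` is empty for wildcards, a single residue for ``fixed`` and a
    tuple of distinct standard residues otherwise. Written order is
    preserved (exchange-scan brackets put the original residue first, as in
    ``[LA]``), so rendering reproduces the input string.
    """

    kind: Literal["wildcard", "fixed", "include", "exclude"]
    residues: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind == "wildcard":
            if self.residues:
                raise ValueError("wildcard class carries no residues")
        elif self.kind == "fixed":
            if len(self.residues) != 1:
                raise ValueError("fixed class requires exactly one residue")
        else:
            if len(self.residues) < 1:
                raise ValueError(f"{self.kind} class requires >=1 residue")
        bad = [r for r in self.residues if r not in _AA_SET]
        if bad:
            raise ValueError(f"non-standard residues in class: {bad}")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("duplicate residues in class")

    def matches(self, residue: str) -> bool:
        """True if a single standard residue satisfies this class."""
        if self.kind == "wildcard":
            return True
        if self.kind == "fixed":
            return residue == self.residues[0]
        if self.kind == "include":
            return residue in self.residues
        return residue not in self.residues

    def render(self) -> str:
        if self.kind == "wildcard":
            return "X"
        if self.kind == "fixed":
            return self.residues[0]
        if self.kind == "include":
            return "[" + "".join(self.residues) + "]"
        return "{" + "".join(self.residues) + "}"

    @property
    def n_allowed(self) -> int:
        """Number of standard residues satisfying the class (for rate math)."""
        if self.kind == "wildcard":
            return 20
        if self.kind == "fixed":
            return 1
        if self.kind == "include":
            return len(self.residues)
        return 20 - len(self.residues)


def wildcard() -> ResidueClass:
    return ResidueClass("wildcard")


def fixed(residue: str) -> ResidueClass:
    return ResidueClass("fixed", (residue.upper(),))


def include(residues: Iterable[str]) -> ResidueClass:
    return ResidueClass("include", tuple(r.upper() for r in residues))


def exclude(residues: Iterable[str]) -> ResidueClass:
    return ResidueClass("exclude", tuple(r.upper() for r in residues))


@dataclass(frozen=True)
class MotifPattern:
    """An ordered, fixed-length sequence of residue classes."""

    positions: tuple[ResidueClass, ...]

    def __post_init__(self):
        if len(self.positions) < 1:
            raise ValueError("pattern must have >=1 position")

    @property
    def length(self) -> int:
        return len(self.positions)

    def render(self) -> str:
        """Canonical uppercase hyphenated PROSITE-style string."""
        return "-".join(c.render() for c in self.positions)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    def match_probability(self, frequencies: dict[str, float] | None = None) -> float:
        """Per-window match probability under i.i.d. residues.

        With ``frequencies`` omitted the 20 residues are taken as uniform,
        so each class contributes ``n_allowed / 20``.
        """
        p = 1.0
        for cls in self.positions:
            if frequencies is None:
                p *= cls.n_allowed / 20.0
            else:
                p *= sum(f for r, f in frequencies.items() if cls.matches(r))
        return p


def parse_pattern(text: str) -> MotifPattern:
    """Parse a PROSITE-style pattern string into a :class:`MotifPattern`.

    Case-insensitive; a trailing period (PROSITE convention) is tolerated.
    Raises :class:`PatternParseError` (with the 1-based element index) for
    unknown characters, empty elements or empty brackets.
    """
    stripped = text.strip()
    if stripped.endswith("."):
        stripped = stripped[:-1]
    if not stripped:
        raise PatternParseError("empty pattern")
    classes: list[ResidueClass] = []
    for i, element in enumerate(stripped.split("-"), start=1):
        element = element.strip().upper()
        if not element:
            raise PatternParseError("empty element", i)
        if element == "X":
            classes.append(wildcard())
        elif len(element) == 1:
            if element not in _AA_SET:
                raise PatternParseError(f"unknown residue {element!r}", i)
            classes.append(fixed(element))
        elif element[0] == "[" and element[-1] == "]":
            inner = element[1:-1]
            if not inner:
                raise PatternParseError("empty inclusion brackets", i)
            if any(r not in _AA_SET for r in inner):
                raise PatternParseError(f"unknown residue in {element!r}", i)
            if len(set(inner)) != len(inner):
                raise PatternParseError(f"duplicate residue in {element!r}", i)
            classes.append(include(inner))
        elif element[0] == "{" and element[-1] == "}":
            inner = element[1:-1]
            if not inner:
                raise PatternParseError("empty exclusion braces", i)
            if any(r not in _AA_SET for r in inner):
                raise PatternParseError(f"unknown residue in {element!r}", i)
            if len(set(inner)) != len(inner):
                raise PatternParseError(f"duplicate residue in {element!r}", i)
            classes.append(exclude(inner))
        else:
            raise PatternParseError(f"unrecognized element {element!r}", i)
    return MotifPattern(tuple(classes))


# ---------------------------------------------------------------------------
# Database records and scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """A FASTA record: first header token as identifier, uppercased sequence."""

    identifier: str
    sequence: str

    def __post_init__(self):
        if not self.identifier:
            raise ValueError("empty protein identifier")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class MotifHit:
    """A matching window: 0-based half-open ``[offset, offset + len(peptide))``."""

    protein_id: str
    offset: int
    peptide: str

    @property
    def start_1based(self) -> int:
        return self.offset + 1

    @property
    def end_1based(self) -> int:
        return self.offset + len(self.peptide)


def read_fasta(path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped) multi-record protein FASTA."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(identifier=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(records: Sequence[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _window_standard(peptide: str) -> bool:
    return all(r in _AA_SET for r in peptide)


def match_window(
    pattern: MotifPattern,
    peptide: str,
    nonstandard: NonstandardPolicy = "skip",
) -> bool:
    """True iff ``peptide`` satisfies every position class of ``pattern``.

    ``peptide`` must have exactly ``pattern.length`` residues. Windows holding
    non-standard residues (B, J, O, U, X, Z, ``*``, ...) fail under the
    default ``skip`` policy and under ``wildcard-fail``; the ``error`` policy
    raises :class:`NonstandardResidueError` instead.
    """
    peptide = peptide.upper()
    if len(peptide) != pattern.length:
        raise ValueError(
            f"window length {len(peptide)} != pattern length {pattern.length}"
        )
    if not _window_standard(peptide):
        if nonstandard == "error":
            raise NonstandardResidueError(f"non-standard residue in {peptide!r}")
        return False
    return all(cls.matches(r) for cls, r in zip(pattern.positions, peptide))


@dataclass
class ScanResult:
    """All matching windows plus the deduplicated peptide set and window tally."""

    hits: list[MotifHit]
    unique_peptides: set[str]
    windows_scanned: int

    def summary(self) -> dict:
        return {
            "windows_scanned": self.windows_scanned,
            "hit_count": len(self.hits),
            "unique_peptide_count": len(self.unique_peptides),
        }


def scan_database(
    db: Sequence[ProteinRecord],
    pattern: MotifPattern,
    nonstandard: NonstandardPolicy = "skip",
) -> ScanResult:
    """Enumerate every pattern-matching window in every record.

    Overlapping matches are all reported, ordered by (record order, offset);
    ``unique_peptides`` deduplicates the matched strings — the "different
    peptides" count. Records shorter than the pattern contribute zero
    windows. Under the ``skip`` policy windows with non-standard residues are
    excluded from ``windows_scanned``; under ``wildcard-fail`` they are
    counted but cannot match.
    """
    L = pattern.length
    hits: list[MotifHit] = []
    uniques: set[str] = set()
    windows = 0
    for rec in db:
        seq = rec.sequence
        for off in range(len(seq) - L + 1):
            window = seq[off : off + L]
            if not _window_standard(window):
                if nonstandard == "error":
                    raise NonstandardResidueError(
                        f"non-standard residue in {rec.identifier} at offset {off}"
                    )
                if nonstandard == "wildcard-fail":
                    windows += 1
                continue
            windows += 1
            if all(cls.matches(r) for cls, r in zip(pattern.positions, window)):
                hits.append(MotifHit(rec.identifier, off, window))
                uniques.add(window)
    return ScanResult(hits=hits, unique_peptides=uniques, windows_scanned=windows)


def write_hits_tsv(result: ScanResult, path) -> None:
    """Hits as TSV with 1-based inclusive coordinates for human consumption."""
    with open(path, "w") as fh:
        fh.write("protein_id\tstart_1based\tend_1based\tpeptide\n")
        for h in result.hits:
            fh.write(f"{h.protein_id}\t{h.start_1based}\t{h.end_1based}\t{h.peptide}\n")


def write_scan_summary(result: ScanResult, path, pattern: MotifPattern) -> None:
    payload = {"pattern": pattern.render(), **result.summary()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
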