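"""Exchange-scan ELISpot analysis and recognition-motif derivation.

An amino-acid exchange scan probes TCR/pMHC contact positions: each position
of the antigenic peptide is substituted in turn (alanine, or serine/threonine
where the original residue is already alanine) and T-cell recognition of the
variant is read out as IFNγ ELISpot spot counts. Positions whose substitution
abolishes recognition are crucial for the interaction and stay fixed in the
recognition motif; positions tolerating substitution become wildcards; an
intermediate "partial" band becomes a two-residue bracket class
(original + substituted), which is how patterns such as X-L-X-X-X-X-F-X-[LA]
arise from a nonamer scan.

Recognition calling is threshold-based on the background-subtracted activity
relative to the original peptide:

    relative_activity = max(0, mean(variant) - mean(background))
                        / (mean(original) - mean(background))

    call = abolished   if relative_activity < low      (default 0.25)
           partial     if low <= relative_activity < high  (default 0.75)
           unaffected  otherwise

Scan-table TSV layout: header ``row_type  position  original_residue
substituted_residue  rep1..repN``; the ``original`` row carries the full
peptide sequence in the ``original_residue`` column, the ``background`` row
(unpulsed or irrelevant-peptide control) leaves the residue columns blank,
and each ``variant`` row gives the 1-based position, the original residue at
that position and the substituted residue. An optional comment line
``# name: <label>`` and ``# pulse_concentration_uM: <value>`` carry metadata.
"""

from __future__ import annotations

import json
import re
import statistics
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .motif_engine import (
    MotifPattern,
    ResidueClass,
    _AA_SET,
    fixed,
    include,
    wildcard,
)

Call = Literal["abolished", "partial", "unaffected"]

DEFAULT_LOW = 0.25
DEFAULT_HIGH = 0.75


class ScanTableError(ValueError):
    """Structural or validation problem in a scan table (names the row)."""


class AssayFailedError(ValueError):
    """Original-peptide response does not exceed background."""


class MotifAmbiguityError(ValueError):
    """Conflicting recognition calls at one peptide position."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peptide:
    """A named peptide over the 20 standard one-letter residue codes."""

    name: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        bad = [r for r in self.sequence if r not in _AA_SET]
        if bad:
            raise ValueError(f"non-standard residue {bad[0]!r} in {self.name!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantRow:
    """One single-position substitution with its replicate spot counts."""

    position: int  # 1-based
    substituted_residue: str
    spot_counts: tuple[int, ...]


@dataclass(frozen=True)
class ExchangeScanTable:
    original: Peptide
    variants: tuple[VariantRow, ...]
    original_counts: tuple[int, ...]
    background_counts: tuple[int, ...]
    pulse_concentration_uM: float | None = None

    def __post_init__(self):
        n = len(self.original)
        if not self.original_counts or not self.background_counts:
            raise ScanTableError("original and background rows need >=1 replicate")
        for counts, label in [
            (self.original_counts, "original"),
            (self.background_counts, "background"),
        ]:
            if any(c < 0 for c in counts):
                raise ScanTableError(f"negative count in {label} row")
        seen: set[tuple[int, str]] = set()
        for v in self.variants:
            if not (1 <= v.position <= n):
                raise ScanTableError(
                    f"variant position {v.position} outside 1..{n}"
                )
            if v.substituted_residue not in _AA_SET:
                raise ScanTableError(
                    f"non-standard substituted residue {v.substituted_residue!r} "
                    f"at position {v.position}"
                )
            if v.substituted_residue == self.original.sequence[v.position - 1]:
                raise ScanTableError(
                    f"substitution at position {v.position} equals original residue"
                )
            if not v.spot_counts:
                raise ScanTableError(f"variant at position {v.position}: no replicates")
            if any(c < 0 for c in v.spot_counts):
                raise ScanTableError(f"negative count at position {v.position}")
            key = (v.position, v.substituted_residue)
            if key in seen:
                raise ScanTableError(
                    f"duplicate variant (position {v.position}, "
                    f"residue {v.substituted_residue})"
                )
            seen.add(key)


@dataclass(frozen=True)
class RecognitionCall:
    position: int  # 1-based
    substituted_residue: str
    relative_activity: float
    call: Call


@dataclass(frozen=True)
class TitrationCurve:
    """Peptide dose-response: strictly decreasing concentrations, spot counts."""

    concentrations_uM: tuple[float, ...]
    spot_counts: tuple[tuple[int, ...], ...]
    background_counts: tuple[int, ...]

    def __post_init__(self):
        if not self.concentrations_uM:
            raise ValueError("empty titration curve")
        if len(self.concentrations_uM) != len(self.spot_counts):
            raise ValueError("concentration/count length mismatch")
        if any(
            a <= b
            for a, b in zip(self.concentrations_uM, self.concentrations_uM[1:])
        ):
            raise ValueError("concentrations must be strictly decreasing")
        for counts in (*self.spot_counts, self.background_counts):
            if not counts or any(c < 0 for c in counts):
                raise ValueError("each count list needs >=1 non-negative entry")


@dataclass(frozen=True)
class MotifDerivation:
    """Derived motif plus the metadata the pattern itself cannot carry."""

    pattern: MotifPattern
    untested_positions: tuple[int, ...]
    calls: tuple[RecognitionCall, ...]
    mode: str

    def to_json_dict(self) -> dict:
        return {
            "pattern": self.pattern.render(),
            "mode": self.mode,
            "untested_positions": list(self.untested_positions),
            "calls": [
                {
                    "position": c.position,
                    "substituted_residue": c.substituted_residue,
                    "relative_activity": c.relative_activity,
                    "call": c.call,
                }
                for c in self.calls
            ],
        }


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ["row_type", "position", "original_residue", "substituted_residue"]


def parse_scan_table(path) -> ExchangeScanTable:
    """Parse the documented scan-table TSV into a validated table.

    Rows flagged ``original`` and ``background`` route to the corresponding
    fields; structural errors (missing rows, bad header) and validation
    errors (position out of range, non-residue, negative counts) raise
    :class:`ScanTableError` naming the offending line.
    """
    name = "peptide"
    pulse: float | None = None
    header: list[str] | None = None
    original_seq: str | None = None
    original_counts: tuple[int, ...] | None = None
    background_counts: tuple[int, ...] | None = None
    variants: list[VariantRow] = []
    claimed_originals: list[tuple[int, int, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*name\s*:\s*(\S.*)$", line)
                if m:
                    name = m.group(1).strip()
                m = re.match(r"#\s*pulse_concentration_uM\s*:\s*(\S+)", line)
                if m:
                    pulse = float(m.group(1))
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                if header[: len(_REQUIRED_COLUMNS)] != _REQUIRED_COLUMNS:
                    raise ScanTableError(
                        f"line {lineno}: header must start with "
                        f"{_REQUIRED_COLUMNS}, got {header[:4]}"
                    )
                if not any(c.startswith("rep") for c in header[4:]):
                    raise ScanTableError(f"line {lineno}: no rep1..repN columns")
                continue
            row = dict(zip(header, cells))
            reps = _parse_reps(row, header, lineno)
            row_type = row.get("row_type", "").strip()
            if row_type == "original":
                if original_seq is not None:
                    raise ScanTableError(f"line {lineno}: duplicate original row")
                original_seq = row["original_residue"].strip().upper()
                original_counts = reps
            elif row_type == "background":
                if background_counts is not None:
                    raise ScanTableError(f"line {lineno}: duplicate background row")
                background_counts = reps
            elif row_type == "variant":
                try:
                    position = int(row["position"])
                except (KeyError, ValueError):
                    raise ScanTableError(
                        f"line {lineno}: variant row needs an integer position"
                    ) from None
                sub = row.get("substituted_residue", "").strip().upper()
                if len(sub) != 1 or sub not in _AA_SET:
                    raise ScanTableError(
                        f"line {lineno}: bad substituted residue {sub!r}"
                    )
                claimed = row.get("original_residue", "").strip().upper()
                variants.append(VariantRow(position, sub, reps))
                claimed_originals.append((lineno, position, claimed))
            else:
                raise ScanTableError(f"line {lineno}: unknown row_type {row_type!r}")
    if header is None:
        raise ScanTableError("empty file: missing header")
    if original_seq is None or original_counts is None:
        raise ScanTableError("missing original row")
    if background_counts is None:
        raise ScanTableError("missing background row")
    # cross-check each variant row's claimed original residue against the sequence
    for lineno, position, claimed in claimed_originals:
        if claimed and 1 <= position <= len(original_seq):
            if claimed != original_seq[position - 1]:
                raise ScanTableError(
                    f"line {lineno}: original_residue {claimed!r} disagrees with "
                    f"peptide sequence at position {position}"
                )
    table = ExchangeScanTable(
        original=Peptide(name=name, sequence=original_seq),
        variants=tuple(variants),
        original_counts=original_counts,
        background_counts=background_counts,
        pulse_concentration_uM=pulse,
    )
    return table


def _parse_reps(row: dict, header: list[str], lineno: int) -> tuple[int, ...]:
    reps = []
    for col in header:
        if not col.startswith("rep"):
            continue
        cell = row.get(col, "").strip()
        if cell == "":
            continue
        try:
            value = int(cell)
        except ValueError:
            raise ScanTableError(
                f"line {lineno}: non-integer count {cell!r} in {col}"
            ) from None
        if value < 0:
            raise ScanTableError(f"line {lineno}: negative count in {col}")
        reps.append(value)
    if not reps:
        raise ScanTableError(f"line {lineno}: no replicate counts")
    return tuple(reps)


def write_scan_table(table: ExchangeScanTable, path) -> None:
    """Write a table in the TSV layout :func:`parse_scan_table` reads."""
    n_rep = max(
        len(table.original_counts),
        len(table.background_counts),
        *(len(v.spot_counts) for v in table.variants),
    ) if table.variants else max(len(table.original_counts), len(table.background_counts))
    rep_cols = [f"rep{i + 1}" for i in range(n_rep)]

    def fmt(counts):
        cells = [str(c) for c in counts]
        return cells + [""] * (n_rep - len(cells))

    with open(path, "w") as fh:
        fh.write(f"# name: {table.original.name}\n")
        if table.pulse_concentration_uM is not None:
            fh.write(f"# pulse_concentration_uM: {table.pulse_concentration_uM}\n")
        fh.write("\t".join(_REQUIRED_COLUMNS + rep_cols) + "\n")
        fh.write(
            "\t".join(
                ["original", "", table.original.sequence, ""]
                + fmt(table.original_counts)
            )
            + "\n"
        )
        fh.write(
            "\t".join(["background", "", "", ""] + fmt(table.background_counts)) + "\n"
        )
        for v in table.variants:
            orig = table.original.sequence[v.position - 1]
            fh.write(
                "\t".join(
                    ["variant", str(v.position), orig, v.substituted_residue]
                    + fmt(v.spot_counts)
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Recognition calling
# ---------------------------------------------------------------------------


def call_recognition(
    table: ExchangeScanTable,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> list[RecognitionCall]:
    """Call per-variant recognition from background-subtracted mean activity.

    Raises :class:`AssayFailedError` when the original-peptide mean does not
    exceed the background mean (no specific recognition to normalize
    against). Thresholds must satisfy ``0 <= low < high <= 1``.
    """
    if not (0 <= low < high <= 1):
        raise ValueError(f"need 0 <= low < high <= 1, got low={low}, high={high}")
    bg = statistics.fmean(table.background_counts)
    orig = statistics.fmean(table.original_counts)
    if orig <= bg:
        raise AssayFailedError(
            "assay failed: no specific recognition of original peptide "
            f"(original mean {orig:.2f} <= background mean {bg:.2f})"
        )
    denom = orig - bg
    calls = []
    for v in table.variants:
        rel = max(0.0, statistics.fmean(v.spot_counts) - bg) / denom
        if rel < low:
            call: Call = "abolished"
        elif rel < high:
            call = "partial"
        else:
            call = "unaffected"
        calls.append(
            RecognitionCall(
                position=v.position,
                substituted_residue=v.substituted_residue,
                relative_activity=rel,
                call=call,
            )
        )
    return calls


def derive_motif(
    original: Peptide,
    calls: Sequence[RecognitionCall],
    mode: Literal["strict", "conservative"] = "conservative",
) -> MotifDerivation:
    """Derive the PROSITE-style recognition motif from recognition calls.

    Per position: ``abolished`` (crucial) fixes the original residue;
    ``unaffected`` becomes a wildcard; ``partial`` becomes the bracket class
    ``[original, substituted...]`` in conservative mode and a wildcard in
    strict mode; untested positions stay fixed to the original residue and
    are flagged in the returned metadata. Calls at the same position must
    agree in category (partial calls pool their substituted residues);
    disagreement raises :class:`MotifAmbiguityError`. The result is
    independent of call-list order.
    """
    if mode not in ("strict", "conservative"):
        raise ValueError(f"unknown mode {mode!r}")
    by_pos: dict[int, list[RecognitionCall]] = {}
    seen: set[tuple[int, str]] = set()
    for c in calls:
        if not (1 <= c.position <= len(original)):
            raise ValueError(f"call position {c.position} outside peptide")
        key = (c.position, c.substituted_residue)
        if key in seen:
            raise MotifAmbiguityError(
                f"duplicate call for position {c.position} "
                f"substitution {c.substituted_residue}"
            )
        seen.add(key)
        by_pos.setdefault(c.position, []).append(c)

    positions: list[ResidueClass] = []
    untested: list[int] = []
    for pos in range(1, len(original) + 1):
        orig_res = original.sequence[pos - 1]
        here = by_pos.get(pos)
        if not here:
            untested.append(pos)
            positions.append(fixed(orig_res))
            continue
        categories = {c.call for c in here}
        if len(categories) > 1:
            raise MotifAmbiguityError(
                f"conflicting calls at position {pos}: {sorted(categories)}"
            )
        category = categories.pop()
        if category == "abolished":
            positions.append(fixed(orig_res))
        elif category == "unaffected":
            positions.append(wildcard())
        else:  # partial
            if mode == "strict":
                positions.append(wildcard())
            else:
                # field convention: original residue first, as in [LA]
                subs = sorted(
                    {c.substituted_residue for c in here} - {orig_res}
                )
                positions.append(include([orig_res, *subs]))
    ordered = tuple(
        sorted(
            (c for cs in by_pos.values() for c in cs),
            key=lambda c: (c.position, c.substituted_residue),
        )
    )
    return MotifDerivation(
        pattern=MotifPattern(tuple(positions)),
        untested_positions=tuple(untested),
        calls=ordered,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Titration
# ---------------------------------------------------------------------------


def parse_titration_table(path) -> TitrationCurve:
    """Parse a titration TSV: ``concentration_uM  rep1..repN`` plus one
    ``background`` row (the ``concentration_uM`` cell reads ``background``)."""
    header: list[str] | None = None
    points: list[tuple[float, tuple[int, ...]]] = []
    background: tuple[int, ...] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                if header[0] != "concentration_uM":
                    raise ScanTableError(
                        f"line {lineno}: first column must be concentration_uM"
                    )
                continue
            row = dict(zip(header, cells))
            reps = _parse_reps(row, header, lineno)
            label = row["concentration_uM"].strip()
            if label.lower() == "background":
                if background is not None:
                    raise ScanTableError(f"line {lineno}: duplicate background row")
                background = reps
            else:
                points.append((float(label), reps))
    if header is None or not points:
        raise ScanTableError("titration table has no concentration rows")
    if background is None:
        raise ScanTableError("missing background row")
    points.sort(key=lambda p: -p[0])
    return TitrationCurve(
        concentrations_uM=tuple(p[0] for p in points),
        spot_counts=tuple(p[1] for p in points),
        background_counts=background,
    )


def titration_threshold(curve: TitrationCurve, low: float = DEFAULT_LOW) -> float | None:
    """Lowest tested concentration still recognized above the ``low`` fraction.

    Relative activity per concentration is computed against the
    top-concentration response (background-subtracted). Returns ``None`` when
    no concentration qualifies (e.g. all responses at background).
    """
    if not (0 < low < 1):
        raise ValueError(f"low must lie in (0,1), got {low}")
    bg = statistics.fmean(curve.background_counts)
    top = statistics.fmean(curve.spot_counts[0]) - bg
    if top <= 0:
        return None
    qualifying = [
        conc
        for conc, counts in zip(curve.concentrations_uM, curve.spot_counts)
        if max(0.0, statistics.fmean(counts) - bg) / top >= low
    ]
    return min(qualifying) if qualifying else None
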