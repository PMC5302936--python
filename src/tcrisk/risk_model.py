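"""Fratricide / cross-reactivity risk comparison of candidate TCRs.

A TCR whose recognition motif is carried by many proteome peptides, and
whose motif-matching peptides bind the restricting HLA allele well, is more
likely to cross-react — in the extreme, to recognize peptides presented on
sibling T cells and commit fratricide during expansion. This module profiles
each candidate TCR (motif burden + HLA binding-score distribution), compares
profiles pairwise, and ranks candidates by a composite risk index:

    risk = w_burden * log10(burden + 1)
         + w_score  * median(score) / max_possible_score

The index is a screening heuristic, not a calibrated probability; the raw
components are always reported alongside it so the composite is auditable.
Burden counts unique motif-matching peptides *before* any binding-score
filter; the scored list is the *post*-filter subset.
"""

from __future__ import annotations

import json
import math
import statistics
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .mhc_pssm import PSSMMatrix, ScoredPeptide, score_set
from .motif_engine import MotifPattern, ProteinRecord, parse_pattern, scan_database

TestName = Literal["mann_whitney", "t_test"]

DEFAULT_TEST: TestName = "mann_whitney"
DEFAULT_WEIGHTS = (1.0, 1.0)


class ConfigurationError(ValueError):
    """Incompatible analysis inputs (e.g. motif length != matrix length)."""


@dataclass(frozen=True)
class TcrProfile:
    """Per-TCR burden and binding-score profile."""

    tcr_name: str
    motif: MotifPattern
    unique_peptides: frozenset[str]
    scored: tuple[ScoredPeptide, ...]
    matrix_max_score: int
    min_score: int | None = None

    @property
    def burden(self) -> int:
        return len(self.unique_peptides)

    @property
    def scores(self) -> list[int]:
        return [s.score for s in self.scored]

    def summary(self) -> dict:
        scores = self.scores
        out = {
            "tcr_name": self.tcr_name,
            "motif": self.motif.render(),
            "burden": self.burden,
            "score_n": len(scores),
            "min_score_filter": self.min_score,
            "matrix_max_score": self.matrix_max_score,
        }
        if scores:
            q1, med, q3 = np.percentile(scores, [25, 50, 75])
            out.update(
                score_median=float(med),
                score_mean=float(np.mean(scores)),
                score_iqr=[float(q1), float(q3)],
            )
        else:
            out.update(score_median=None, score_mean=None, score_iqr=None)
        return out


def build_profile(
    tcr_name: str,
    motif: MotifPattern,
    db: Sequence[ProteinRecord],
    matrix: PSSMMatrix,
    min_score: int | None = None,
) -> TcrProfile:
    """Scan the database for the motif and score the unique matches.

    Composes :func:`motif_engine.scan_database` and :func:`mhc_pssm.score_set`.
    Burden counts unique peptides before the score filter; ``scored`` holds
    the (optionally filtered) scored subset.
    """
    if motif.length != matrix.length:
        raise ConfigurationError(
            f"motif length {motif.length} != matrix length {matrix.length}"
        )
    result = scan_database(db, motif)
    scored = score_set(matrix, sorted(result.unique_peptides), min_score=min_score)
    return TcrProfile(
        tcr_name=tcr_name,
        motif=motif,
        unique_peptides=frozenset(result.unique_peptides),
        scored=tuple(scored),
        matrix_max_score=matrix.max_score(),
        min_score=min_score,
    )


@dataclass(frozen=True)
class PairwiseComparison:
    """Burden ratio and two-sample score-distribution test for a TCR pair."""

    tcr_a: str
    tcr_b: str
    burden_a: int
    burden_b: int
    burden_ratio: float  # larger burden / smaller burden; inf if smaller is 0
    higher_burden: str | None  # None on tie
    test: TestName | None
    statistic: float | None
    p_value: float | None
    higher_median: str | None
    insufficient_n: bool

    def to_json_dict(self) -> dict:
        d = self.__dict__.copy()
        if d["burden_ratio"] == math.inf:
            d["burden_ratio"] = None
        return d


def compare_profiles(
    a: TcrProfile,
    b: TcrProfile,
    test: TestName = DEFAULT_TEST,
) -> PairwiseComparison:
    """Compare two TCR profiles by burden and score distribution.

    The burden ratio is larger/smaller. The two-sided distribution test
    (rank-based Mann-Whitney by default; Welch-free unpaired two-tailed
    t-test selectable) runs on the score lists when both have >=2 entries;
    otherwise it is skipped with ``insufficient_n=True`` and the burden
    comparison still reported.
    """
    if test not in ("mann_whitney", "t_test"):
        raise ValueError(f"unknown test {test!r}")
    hi, lo = max(a.burden, b.burden), min(a.burden, b.burden)
    if a.burden == b.burden:
        higher_burden = None
    else:
        higher_burden = a.tcr_name if a.burden > b.burden else b.tcr_name
    ratio = math.inf if lo == 0 else hi / lo
    if hi == 0:
        ratio = 1.0  # both empty: no asymmetry

    sa, sb = a.scores, b.scores
    if len(sa) < 2 or len(sb) < 2:
        return PairwiseComparison(
            a.tcr_name, b.tcr_name, a.burden, b.burden, ratio, higher_burden,
            test=None, statistic=None, p_value=None, higher_median=None,
            insufficient_n=True,
        )
    if test == "mann_whitney":
        res = stats.mannwhitneyu(sa, sb, alternative="two-sided")
    else:
        res = stats.ttest_ind(sa, sb, equal_var=True, alternative="two-sided")
    med_a, med_b = statistics.median(sa), statistics.median(sb)
    if med_a == med_b:
        higher_median = None
    else:
        higher_median = a.tcr_name if med_a > med_b else b.tcr_name
    return PairwiseComparison(
        a.tcr_name, b.tcr_name, a.burden, b.burden, ratio, higher_burden,
        test=test, statistic=float(res.statistic), p_value=float(res.pvalue),
        higher_median=higher_median, insufficient_n=False,
    )


def risk_index(
    profile: TcrProfile,
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
) -> float:
    """Composite index: burden term + normalized median-score term.

    Degenerate profiles (no scored peptides, or a zero-max matrix) drop the
    score term, so they rank on burden alone and empty profiles rank lowest.
    """
    burden_w, score_w = weights
    index = burden_w * math.log10(profile.burden + 1)
    scores = profile.scores
    if scores and profile.matrix_max_score > 0:
        index += score_w * statistics.median(scores) / profile.matrix_max_score
    return index


@dataclass
class RiskReport:
    """Full risk report: per-TCR summaries, pairwise tests, ranking, parameters."""

    profiles: list[dict]
    pairwise: list[dict]
    ranking: list[dict]  # descending risk; fields tcr_name, risk_index, burden, ...
    parameters: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "profiles": self.profiles,
                "pairwise": self.pairwise,
                "ranking": self.ranking,
                "parameters": self.parameters,
            },
            indent=indent,
        )

    @classmethod
    def from_json(cls, text: str) -> "RiskReport":
        d = json.loads(text)
        return cls(
            profiles=d["profiles"],
            pairwise=d["pairwise"],
            ranking=d["ranking"],
            parameters=d["parameters"],
        )

    def to_markdown(self) -> str:
        lines = [
            "# TCR cross-reactivity risk report",
            "",
            "| rank | TCR | risk index | burden | scored n | median score |",
            "|---:|---|---:|---:|---:|---:|",
        ]
        for i, row in enumerate(self.ranking, start=1):
            med = row.get("score_median")
            lines.append(
                f"| {i} | {row['tcr_name']} | {row['risk_index']:.3f} "
                f"| {row['burden']} | {row['score_n']} "
                f"| {'-' if med is None else med} |"
            )
        if self.pairwise:
            lines += ["", "## Pairwise comparisons", ""]
            for p in self.pairwise:
                ratio = p["burden_ratio"]
                ratio_s = "inf" if ratio is None else f"{ratio:.1f}"
                if p["insufficient_n"]:
                    test_s = "distribution test skipped (insufficient n)"
                else:
                    test_s = (
                        f"{p['test']} p={p['p_value']:.3g}, "
                        f"higher median: {p['higher_median'] or 'tie'}"
                    )
                lines.append(
                    f"- {p['tcr_a']} vs {p['tcr_b']}: burden "
                    f"{p['burden_a']} vs {p['burden_b']} (ratio {ratio_s}, "
                    f"higher: {p['higher_burden'] or 'tie'}); {test_s}"
                )
        return "\n".join(lines) + "\n"


def rank_risk(
    profiles: Sequence[TcrProfile],
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
    test: TestName = DEFAULT_TEST,
    bonferroni: bool = False,
) -> RiskReport:
    """Rank candidate TCRs by descending composite risk.

    Ties break by burden, then name. All pairwise comparisons are included
    for >=2 profiles; ``bonferroni`` multiplies their p-values by the number
    of pairs (capped at 1) for multi-TCR screens.
    """
    if not profiles:
        raise ValueError("need >=1 profile")
    summaries = [p.summary() for p in profiles]
    indexed = [
        (risk_index(p, weights), p.burden, p.tcr_name, p, s)
        for p, s in zip(profiles, summaries)
    ]
    indexed.sort(key=lambda t: (-t[0], -t[1], t[2]))
    ranking = [
        {"tcr_name": name, "risk_index": float(idx), **summary}
        for idx, _, name, _, summary in indexed
    ]
    pairwise = []
    n_pairs = len(profiles) * (len(profiles) - 1) // 2
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            cmp = compare_profiles(profiles[i], profiles[j], test=test).to_json_dict()
            if bonferroni and cmp["p_value"] is not None:
                cmp["p_value_adjusted"] = min(1.0, cmp["p_value"] * n_pairs)
            pairwise.append(cmp)
    return RiskReport(
        profiles=summaries,
        pairwise=pairwise,
        ranking=ranking,
        parameters={
            "burden_weight": weights[0],
            "score_weight": weights[1],
            "test": test,
            "bonferroni": bonferroni,
        },
    )
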