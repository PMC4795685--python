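"""Nonparametric before/after statistics for delineation harmonization.

The study protocol this reproduces scores every observer's contour against a
reference (a randomly elected observer, or a vote-threshold consensus) in two
delineation rounds — before and after guideline agreement — and asks, per
index, whether the second round improved.  The paired comparison uses the
Wilcoxon signed-rank test, pairing index values by observer; between-case
comparisons of VO and DSC use the Mann-Whitney U test.  Tests are two-sided,
significance is declared at p < 0.05, and no multiple-testing correction is
applied across the five indices or the cases (an optional Holm adjustment is
available).

Conventions: zero differences are dropped (Wilcoxon's zero-drop rule), ties
are mid-ranked, the exact signed-rank null is used for n ≤ 25 without tied
nonzero |differences|, and the exact U null for group sizes ≤ 8 without ties;
otherwise the tie-corrected normal approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .consensus import ConsensusSpec, compare_to_consensus
from .indices import INDEX_NAMES, IndexSet, all_indices
from .mask_core import ObserverSet

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
EXACT_WILCOXON_MAX_N = 25
EXACT_MWU_MAX_N = 8


class DegenerateSampleError(ValueError):
    """The sample carries no information (e.g. all paired differences zero)."""


@dataclass(frozen=True)
class PairedSample:
    """Per-observer index values in two rounds, aligned by observer."""

    observer_ids: tuple[str, ...]
    values_round1: tuple[float, ...]
    values_round2: tuple[float, ...]
    index_name: str = ""

    def __post_init__(self) -> None:
        if not (len(self.observer_ids) == len(self.values_round1) == len(self.values_round2)):
            raise ValueError("observer_ids and both value vectors must have equal length")
        if len(self.observer_ids) < 2:
            raise ValueError("paired sample needs n >= 2 observers")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_effective: tuple[int, ...]
    method_note: str
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def wilcoxon_paired(sample: PairedSample, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on round-2 minus round-1 differences.

    Zero differences are dropped; the exact null distribution is used when the
    effective n is ≤ 25 and no nonzero |difference| is tied, otherwise the
    normal approximation with tie correction.
    """
    d = np.asarray(sample.values_round2, dtype=float) - np.asarray(
        sample.values_round1, dtype=float)
    nonzero = d[d != 0]
    if nonzero.size == 0:
        raise DegenerateSampleError(
            f"all {d.size} paired differences are zero for index "
            f"{sample.index_name or '?'} — the signed-rank test is undefined"
        )
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    exact = nonzero.size <= EXACT_WILCOXON_MAX_N and not has_ties
    method = "exact" if exact else "approx"
    res = stats.wilcoxon(
        sample.values_round2, sample.values_round1,
        zero_method="wilcox", correction=False, alternative="two-sided",
        method=method,
    )
    note = ("exact signed-rank null" if exact
            else "normal approximation with tie correction")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_effective=(int(nonzero.size),),
        method_note=note,
        alpha=alpha,
    )


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float],
                 alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Two-sided Mann-Whitney U test for two unpaired samples."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateSampleError(
            f"each group needs n >= 2 values, got {a.size} and {b.size}")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        # every value tied: U is at its null mean and carries no evidence
        return TestResult(statistic=a.size * b.size / 2.0, p_value=1.0,
                          n_effective=(int(a.size), int(b.size)),
                          method_note="degenerate: all values identical", alpha=alpha)
    has_ties = np.unique(pooled).size < pooled.size
    exact = max(a.size, b.size) <= EXACT_MWU_MAX_N and not has_ties
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=False)
    note = "exact U null" if exact else "tie-corrected normal approximation"
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_effective=(int(a.size), int(b.size)),
        method_note=note,
        alpha=alpha,
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; off by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def summarize_round(indexsets: Sequence[IndexSet]) -> dict[str, tuple[float, float]]:
    """Per-index mean and sample SD (n−1 denominator) over a round's IndexSets."""
    if len(indexsets) < 2:
        raise DegenerateSampleError(
            f"need >= 2 index records to compute an SD, got {len(indexsets)}")
    out = {}
    for name in INDEX_NAMES:
        vals = np.array([s.value(name) for s in indexsets], dtype=float)
        out[name] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


@dataclass
class ComparisonReport:
    """Two-round comparison for one case: summaries, per-index paired tests."""

    case_id: str
    mode: Literal["reference", "consensus"]
    round_ids: tuple[str, str]
    indexsets: dict[str, list[IndexSet]]            # round_id -> records
    summaries: dict[str, dict[str, tuple[float, float]]]  # round_id -> index -> (mean, sd)
    tests: dict[str, Optional[TestResult]]          # index -> result (None if degenerate)
    degenerate: dict[str, str] = field(default_factory=dict)  # index -> reason

    def summary_frame(self, digits: int = 2):
        """Mean (±SD) table, one row per round, one column per index."""
        import pandas as pd

        rows = []
        for rid in self.round_ids:
            row = {"case_id": self.case_id, "round_id": rid}
            for name in INDEX_NAMES:
                mean, sd = self.summaries[rid][name]
                row[name] = f"{round(mean, digits):.{digits}f} (±{round(sd, digits):.{digits}f})"
            rows.append(row)
        return pd.DataFrame(rows)

    def to_text_table(self, digits: int = 2) -> str:
        """Render in the classic report layout: rows = rounds, columns = indices,
        p-values beneath the second-round cells."""
        header = ["case", "comparison"] + [n.upper() + " (±SD)" for n in INDEX_NAMES]
        lines = ["\t".join(header)]
        for k, rid in enumerate(self.round_ids):
            cells = [self.case_id if k == 0 else "", f"comparison {k + 1}"]
            for name in INDEX_NAMES:
                mean, sd = self.summaries[rid][name]
                cell = f"{mean:.{digits}f} (±{sd:.{digits}f})"
                if k == 1:
                    t = self.tests.get(name)
                    cell += f" p = {t.p_value:.4g}" if t else " p = n/a (degenerate)"
                cells.append(cell)
            lines.append("\t".join(cells))
        return "\n".join(lines)


def _reference_indexsets(obs_set: ObserverSet, case_id: str, round_id: str) -> list[IndexSet]:
    ref_id = obs_set.reference_observer
    if ref_id is None:
        raise ValueError("reference mode requires a designated reference observer")
    reference = obs_set.get(ref_id, case_id, round_id)
    out = []
    for observer_id, mask in obs_set.select(case_id, round_id, exclude=(ref_id,)).items():
        out.append(all_indices(mask, reference, test_id=observer_id,
                               reference_id=ref_id, case_id=case_id, round_id=round_id))
    return out


def indexsets_for_round(
    obs_set: ObserverSet,
    case_id: str,
    round_id: str,
    mode: Literal["reference", "consensus"],
    spec: Optional[ConsensusSpec] = None,
) -> list[IndexSet]:
    """Score one (case, round): every observer against reference or consensus.

    In reference mode the reference observer's self-comparison is excluded
    (it is identically optimal and would dilute the variability estimate).
    """
    if mode == "reference":
        return _reference_indexsets(obs_set, case_id, round_id)
    if mode == "consensus":
        if spec is None:
            spec = ConsensusSpec(case_id=case_id, round_id=round_id)
        else:
            spec = ConsensusSpec(case_id=case_id, round_id=round_id,
                                 threshold_count=spec.threshold_count,
                                 leave_one_out=spec.leave_one_out)
        return compare_to_consensus(obs_set, spec)
    raise ValueError(f"unknown mode {mode!r}")


def compare_rounds(
    obs_set: ObserverSet,
    case_id: str,
    mode: Literal["reference", "consensus"] = "reference",
    spec: Optional[ConsensusSpec] = None,
    round_ids: Optional[tuple[str, str]] = None,
    alpha: float = DEFAULT_ALPHA,
) -> ComparisonReport:
    """Quantify harmonization: per-round index summaries plus one Wilcoxon
    signed-rank test per index, pairing values by observer.

    Observers present in only one round are dropped with a logged warning.
    An index whose paired differences are all zero is reported as degenerate
    (no test result) rather than failing the whole comparison.
    """
    if round_ids is None:
        rids = obs_set.rounds(case_id)
        if len(rids) != 2:
            raise ValueError(
                f"case {case_id!r} has rounds {rids}; specify round_ids explicitly")
        round_ids = (rids[0], rids[1])

    per_round: dict[str, dict[str, IndexSet]] = {}
    for rid in round_ids:
        records = indexsets_for_round(obs_set, case_id, rid, mode, spec)
        per_round[rid] = {rec.test_id: rec for rec in records}

    r1, r2 = round_ids
    common = [o for o in per_round[r1] if o in per_round[r2]]
    dropped = (set(per_round[r1]) | set(per_round[r2])) - set(common)
    if dropped:
        logger.warning("case %s: dropped %d observer(s) present in only one round: %s",
                       case_id, len(dropped), sorted(dropped))
    if len(common) < 2:
        raise DegenerateSampleError(
            f"case {case_id!r}: only {len(common)} observer(s) present in both rounds")

    indexsets = {rid: [per_round[rid][o] for o in common] for rid in round_ids}
    summaries = {rid: summarize_round(indexsets[rid]) for rid in round_ids}

    tests: dict[str, Optional[TestResult]] = {}
    degenerate: dict[str, str] = {}
    for name in INDEX_NAMES:
        sample = PairedSample(
            observer_ids=tuple(common),
            values_round1=tuple(per_round[r1][o].value(name) for o in common),
            values_round2=tuple(per_round[r2][o].value(name) for o in common),
            index_name=name,
        )
        try:
            tests[name] = wilcoxon_paired(sample, alpha=alpha)
        except DegenerateSampleError as exc:
            tests[name] = None
            degenerate[name] = str(exc)
            logger.warning("case %s index %s: %s", case_id, name, exc)

    return ComparisonReport(
        case_id=case_id, mode=mode, round_ids=round_ids,
        indexsets=indexsets, summaries=summaries, tests=tests, degenerate=degenerate,
    )


def compare_between_cases(
    obs_set: ObserverSet,
    case_a: str,
    case_b: str,
    round_id: str,
    index_name: Literal["vo", "dsc"] = "dsc",
    mode: Literal["reference", "consensus"] = "reference",
    spec: Optional[ConsensusSpec] = None,
    alpha: float = DEFAULT_ALPHA,
) -> TestResult:
    """Mann-Whitney comparison of one index between two cases in one round."""
    vals_a = [s.value(index_name)
              for s in indexsets_for_round(obs_set, case_a, round_id, mode, spec)]
    vals_b = [s.value(index_name)
              for s in indexsets_for_round(obs_set, case_b, round_id, mode, spec)]
    return mann_whitney(vals_a, vals_b, alpha=alpha)
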