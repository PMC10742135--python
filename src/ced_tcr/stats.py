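"""Repertoire summary statistics and CeD-vs-control group comparisons.

Per-sample diversity (richness, Shannon, Gini-Simpson), V/J gene-segment
usage proportions, and two-sided equal-variance Student t-tests with a
family-wise Bonferroni correction.  The Bonferroni family is all segments
of one family (TRAV, TRAJ, TRBV or TRBJ) tested for one chain; the three
diversity measures form their own family of m = 3.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .types import Cohort, Repertoire

logger = logging.getLogger(__name__)

SEGMENT_FAMILIES = ("TRAV", "TRAJ", "TRBV", "TRBJ")
DIVERSITY_MEASURES = ("richness", "shannon", "simpson")


@dataclass
class DiversityProfile:
    """Richness (clone count), Shannon entropy (nats) and Gini-Simpson
    diversity of one repertoire, computed on read-fraction weights."""

    sample_id: str
    richness: int
    shannon: float
    simpson: float


@dataclass
class GroupTestResult:
    feature: str
    family: str
    t_statistic: float
    p_unadjusted: float
    p_adjusted: float
    m: int


def diversity_profile(rep: Repertoire) -> DiversityProfile:
    """Diversity of one repertoire; an empty repertoire scores zero on all
    three measures (with a warning)."""
    if rep.n_clones == 0:
        logger.warning("repertoire %s is empty; diversity set to 0", rep.sample_id)
        return DiversityProfile(rep.sample_id, 0, 0.0, 0.0)
    counts = np.array([c.count for c in rep.clones], dtype=float)
    p = counts / counts.sum()
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p**2).sum())
    return DiversityProfile(rep.sample_id, rep.n_clones, shannon, simpson)


def diversity_table(cohort: Cohort, chain: str) -> pd.DataFrame:
    rows = [
        diversity_profile(rep).__dict__
        for rep in cohort.repertoires
        if rep.chain == chain
    ]
    return pd.DataFrame(rows, columns=["sample_id", "richness", "shannon", "simpson"])


def segment_usage(cohort: Cohort, family: str, weight: str = "reads") -> pd.DataFrame:
    """Per-sample segment usage proportions for one gene-segment family.

    Rows are samples of the family's chain, columns the segments of that
    family observed anywhere in the cohort; each row sums to 1.  ``weight``
    is ``"reads"`` (fraction of productive reads, the default) or
    ``"clones"`` (fraction of distinct clones).
    """
    if family not in SEGMENT_FAMILIES:
        raise ValueError(f"family must be one of {SEGMENT_FAMILIES}, got {family!r}")
    if weight not in ("reads", "clones"):
        raise ValueError(f"weight must be 'reads' or 'clones', got {weight!r}")
    chain = family[:3]
    attr = "v_segment" if family.endswith("V") else "j_segment"
    reps = [r for r in cohort.repertoires if r.chain == chain and r.n_clones > 0]
    if not reps:
        raise ValueError(f"no non-empty {chain} repertoires in cohort {cohort.name}")
    segments: list[str] = []
    per_sample: list[dict[str, float]] = []
    for rep in reps:
        totals: dict[str, float] = {}
        for c in rep.clones:
            seg = getattr(c, attr)
            totals[seg] = totals.get(seg, 0.0) + (c.count if weight == "reads" else 1.0)
        per_sample.append(totals)
        for seg in totals:
            if seg not in segments:
                segments.append(seg)
    segments.sort()
    mat = pd.DataFrame(
        0.0, index=[r.sample_id for r in reps], columns=segments
    )
    for rep, totals in zip(reps, per_sample):
        denom = sum(totals.values())
        for seg, v in totals.items():
            mat.loc[rep.sample_id, seg] = v / denom
    return mat


def group_t_test(
    values_ced: Sequence[float], values_ctrl: Sequence[float]
) -> tuple[float, float]:
    """Two-sided equal-variance two-sample Student t-test.

    Raises ``ValueError`` when either group has fewer than two values or the
    pooled variance is zero (undefined statistic).
    """
    a = np.asarray(values_ced, dtype=float)
    b = np.asarray(values_ctrl, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled == 0.0:
        raise ValueError("zero pooled variance: t statistic undefined")
    res = sp_stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(p: float, m: int) -> float:
    """Family-wise adjusted p-value min(1, m * p)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError(f"family size must be >= 1, got {m}")
    return min(1.0, m * p)


def _split_groups(
    values: pd.Series, labels: dict[str, str]
) -> tuple[list[float], list[float]]:
    ced = [values[s] for s in values.index if labels.get(s) == "CeD"]
    ctrl = [values[s] for s in values.index if labels.get(s) == "control"]
    return ced, ctrl


def segment_usage_tests(
    cohort: Cohort, family: str, weight: str = "reads"
) -> list[GroupTestResult]:
    """Test every segment of one family for a CeD-vs-control usage difference.

    Segments observed in zero samples of either group are excluded from
    testing and from the Bonferroni family size m.  Segments whose pooled
    variance is zero are skipped with a warning (and removed from m).
    """
    usage = segment_usage(cohort, family, weight=weight)
    labels = cohort.labels()
    testable: list[tuple[str, list[float], list[float]]] = []
    for seg in usage.columns:
        ced, ctrl = _split_groups(usage[seg], labels)
        if len(ced) < 2 or len(ctrl) < 2:
            continue
        if not any(v > 0 for v in ced) or not any(v > 0 for v in ctrl):
            continue
        testable.append((seg, ced, ctrl))
    results: list[GroupTestResult] = []
    m = len(testable)
    for seg, ced, ctrl in testable:
        try:
            t, p = group_t_test(ced, ctrl)
        except ValueError:
            logger.warning("segment %s skipped: degenerate variance", seg)
            m -= 1
            continue
        results.append(GroupTestResult(seg, family, t, p, math.nan, m))
    for r in results:
        r.m = m
        r.p_adjusted = bonferroni_adjust(r.p_unadjusted, m)
    return results


def diversity_tests(cohort: Cohort, chain: str) -> list[GroupTestResult]:
    """CeD-vs-control t-tests for the three diversity measures (family m=3)."""
    table = diversity_table(cohort, chain).set_index("sample_id")
    labels = cohort.labels()
    results = []
    m = len(DIVERSITY_MEASURES)
    for measure in DIVERSITY_MEASURES:
        ced, ctrl = _split_groups(table[measure], labels)
        try:
            t, p = group_t_test(ced, ctrl)
        except ValueError as exc:
            logger.warning("diversity measure %s skipped: %s", measure, exc)
            continue
        results.append(
            GroupTestResult(measure, "diversity", t, p, bonferroni_adjust(p, m), m)
        )
    return results


def tests_to_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "t": r.t_statistic,
                "p": r.p_unadjusted,
                "p_adj": r.p_adjusted,
                "m": r.m,
                "family": r.family,
            }
            for r in results
        ],
        columns=["feature", "t", "p", "p_adj", "m", "family"],
    )
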