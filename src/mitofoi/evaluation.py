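"""Comparison machinery: correlation, Cohen's kappa, grade grouping, and
percentile scoring of rater/algorithm FOI selections.

A selection is scored against the full distribution of ground-truth mitotic
counts achievable over all valid FOI placements on the slide: whether the
selected count reaches the upper half or the upper quarter of that
distribution, and whether it clears the grading threshold (MC >= 7 per
10 HPF in Kiupel's scheme).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationSet, RaterGroup, RaterSelection
from .density import GridSpec, mc_distribution
from .estimators import oracle_density
from .foi_select import evaluate_selection
from .geometry import FOIShape, SlideGeometry
from .tissue import TissueMask, ValidMask, valid_mask

__all__ = [
    "GradeGroup",
    "CaseReport",
    "pearson_corr",
    "spearman_corr",
    "cohen_kappa",
    "grade_group",
    "percentile_score",
    "rater_report",
]

#: Grading threshold: at least seven mitotic figures per 10 HPF.
DEFAULT_THRESHOLD = 7

#: Fraction of above-threshold placements required for "clearly high grade".
DEFAULT_HIGH_FRAC = 0.75


class GradeGroup(str, enum.Enum):
    """Case grouping by how position-sensitive the grading decision is."""

    CLEARLY_LOW = "clearly_low"
    BORDERLINE = "borderline"
    CLEARLY_HIGH = "clearly_high"


@dataclass
class CaseReport:
    """Per-slide evaluation: achievable-MC distribution summary, grade group,
    and each rater's selected count with its derived flags."""

    slide_id: str
    grade_group: GradeGroup
    dist_min: float
    dist_q25: float
    dist_median: float
    dist_q75: float
    dist_max: float
    # one entry per selection: (rater_id, group, gt_mc, above_threshold, top_half, top_quarter)
    raters: list[tuple[str, RaterGroup, int, bool, bool, bool]] = field(default_factory=list)


def pearson_corr(xs, ys) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("inputs must be 1-D of equal length")
    if len(xs) < 2:
        raise ValueError("need at least two observations")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    from scipy import stats

    return float(stats.pearsonr(xs, ys).statistic)


def spearman_corr(xs, ys) -> float:
    """Spearman rank correlation (offered as a robust alternative)."""
    from scipy import stats

    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    if xs.shape != ys.shape or xs.ndim != 1 or len(xs) < 2:
        raise ValueError("inputs must be 1-D of equal length >= 2")
    return float(stats.spearmanr(xs, ys).statistic)


def cohen_kappa(a, b) -> float:
    """Cohen's kappa: chance-corrected agreement between two label lists.

    kappa = (p_o - p_e) / (1 - p_e) with p_e the marginal-product expected
    agreement. In the degenerate case p_e = 1 (both raters constant on the
    same label pool), returns 1 if the observed agreement is perfect, else 0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label lists must be 1-D of equal length")
    if len(a) == 0:
        raise ValueError("label lists must be non-empty")
    labels = np.unique(np.concatenate([a, b]))
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == l) for l in labels])
    pb = np.array([np.mean(b == l) for l in labels])
    p_e = float(pa @ pb)
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def grade_group(
    dist,
    threshold: int = DEFAULT_THRESHOLD,
    high_frac: float = DEFAULT_HIGH_FRAC,
) -> GradeGroup:
    """Group a slide by its achievable-MC distribution.

    Clearly low grade: every possible count is below the threshold. Clearly
    high grade: strictly more than ``high_frac`` of the possible counts reach
    it. Everything else is borderline — there the FOI placement decides the
    grading call.
    """
    dist = np.asarray(dist, dtype=np.float64)
    if dist.size == 0:
        raise ValueError("empty mitotic-count distribution")
    frac_ge = float(np.mean(dist >= threshold))
    if frac_ge == 0.0:
        return GradeGroup.CLEARLY_LOW
    if frac_ge > high_frac:
        return GradeGroup.CLEARLY_HIGH
    return GradeGroup.BORDERLINE


def percentile_score(selected_mc: float, dist) -> tuple[bool, bool]:
    """Whether a selected count reaches the upper half / upper 25% of the distribution.

    Percentiles are order statistics (inverted-CDF): the p-th percentile is
    the smallest distribution value with at least a fraction p of the mass at
    or below it, so "upper 25%" means at or above the 75th order statistic.
    """
    dist = np.asarray(dist, dtype=np.float64)
    if dist.size == 0:
        raise ValueError("empty mitotic-count distribution")
    med = np.percentile(dist, 50, method="inverted_cdf")
    q75 = np.percentile(dist, 75, method="inverted_cdf")
    return bool(selected_mc >= med), bool(selected_mc >= q75)


def _wilson_ci(k: int, n: int) -> tuple[float, float]:
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def rater_report(
    sets: list[AnnotationSet],
    selections: list[RaterSelection],
    shape: FOIShape,
    stride: int = 50,
    tissues: dict[str, TissueMask] | None = None,
    threshold: int = DEFAULT_THRESHOLD,
    high_frac: float = DEFAULT_HIGH_FRAC,
    coverage: float = 0.95,
    kappa_mode: str = "vs_truth",
) -> tuple[list[CaseReport], dict]:
    """Score every rater selection against each slide's achievable-MC distribution.

    For each slide, the position-dependent ground-truth MC map is computed on
    a grid of the given stride, restricted to the valid mask (from the
    provided tissue mask, or all-tissue if none is given), and every
    selection on that slide is scored. Group summaries give, per rater group,
    the proportion of selections in the upper half / upper quarter with 95%
    Wilson intervals, and an above-threshold agreement kappa: ``vs_truth``
    compares each selection's flag against whether the slide's maximal count
    clears the threshold; ``pairwise`` averages kappa over rater pairs within
    the group (on slides both rated).

    Raises on a selection referencing an unknown slide id.
    """
    by_slide = {s.slide_id: s for s in sets}
    for sel in selections:
        if sel.slide_id not in by_slide:
            raise ValueError(f"selection references unknown slide {sel.slide_id!r}")

    reports: list[CaseReport] = []
    flags: dict[RaterGroup, list[tuple[bool, bool, bool, bool]]] = {}
    per_rater: dict[tuple[RaterGroup, str], dict[str, bool]] = {}
    truth_by_slide: dict[str, bool] = {}

    for aset in sets:
        g = aset.geometry
        grid = GridSpec.cover(g, stride)
        est = oracle_density(aset, shape, grid)
        if tissues is not None and aset.slide_id in tissues:
            tm = tissues[aset.slide_id]
        else:
            ds = max(1, min(32, g.width_px // 8, g.height_px // 8))
            tm = TissueMask(
                mask=np.ones((-(-g.height_px // ds), -(-g.width_px // ds)), dtype=bool),
                downsample=ds,
            )
        vm: ValidMask = valid_mask(tm, grid, shape, coverage=coverage, geometry=g)
        dist = mc_distribution(est.density, vm)
        gg = grade_group(dist, threshold, high_frac)
        q = np.percentile(dist, [25, 50, 75], method="inverted_cdf")
        truth_by_slide[aset.slide_id] = bool(dist.max() >= threshold)

        report = CaseReport(
            slide_id=aset.slide_id,
            grade_group=gg,
            dist_min=float(dist.min()),
            dist_q25=float(q[0]),
            dist_median=float(q[1]),
            dist_q75=float(q[2]),
            dist_max=float(dist.max()),
        )
        for sel in selections:
            if sel.slide_id != aset.slide_id:
                continue
            gt = evaluate_selection(aset, sel, shape)
            above = gt >= threshold
            top_half, top_quarter = percentile_score(gt, dist)
            report.raters.append(
                (sel.rater_id, sel.rater_group, gt, above, top_half, top_quarter)
            )
            flags.setdefault(sel.rater_group, []).append(
                (above, top_half, top_quarter, truth_by_slide[aset.slide_id])
            )
            per_rater.setdefault((sel.rater_group, sel.rater_id), {})[aset.slide_id] = above
        reports.append(report)

    summaries: dict = {}
    for group, entries in flags.items():
        n = len(entries)
        k_half = sum(e[1] for e in entries)
        k_quarter = sum(e[2] for e in entries)
        summary = {
            "n": n,
            "prop_top_half": k_half / n,
            "ci_top_half": _wilson_ci(k_half, n),
            "prop_top_quarter": k_quarter / n,
            "ci_top_quarter": _wilson_ci(k_quarter, n),
        }
        if kappa_mode == "vs_truth":
            a = [e[0] for e in entries]
            b = [e[3] for e in entries]
            summary["kappa"] = cohen_kappa(a, b)
        elif kappa_mode == "pairwise":
            raters = [r for (grp, r) in per_rater if grp == group]
            kappas = []
            for i in range(len(raters)):
                for j in range(i + 1, len(raters)):
                    fi = per_rater[(group, raters[i])]
                    fj = per_rater[(group, raters[j])]
                    common = sorted(set(fi) & set(fj))
                    if common:
                        kappas.append(
                            cohen_kappa([fi[s] for s in common], [fj[s] for s in common])
                        )
            summary["kappa"] = float(np.mean(kappas)) if kappas else float("nan")
        else:
            raise ValueError(f"unknown kappa_mode {kappa_mode!r}")
        summaries[group.value] = summary
    return reports, summaries
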