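"""ROI-level statistics for susceptibility maps.

Two protocols:

* **Orientation-variation (anisotropy) testing.**  Apparent
  susceptibility in oriented white-matter tracts (e.g. the posterior
  limb of the internal capsule, PLIC, or the posterior thalamic
  radiation, PTR) varies with the head orientation relative to B0.
  Given per-orientation value samples from one ROI, a Levene test
  (median-centered, i.e. Brown-Forsythe) first checks homogeneity of
  variances; if its p > 0.05 the one-way ANOVA is the valid omnibus
  test, otherwise the Kruskal-Wallis test is.  The valid test's p-value
  below 0.05 is an anisotropy call.

* **Two-group comparison.**  Patient-vs-control ROI means compared by a
  two-sample t-test (equal-variance Student by default, Welch
  switchable), reported with the percent change of the group means and
  a significance tier: "**" for p < 0.01, "*" for 0.01 <= p < 0.05.

Sampling unit: the value vectors are whatever the caller puts in —
per-voxel values within an ROI (default elsewhere in this package) or
per-subject means.  No multiple-testing correction is applied by
default; a Bonferroni factor is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .kspace_physics import ValidationError

__all__ = [
    "ROISampleSet",
    "MSATestResult",
    "GroupCompareResult",
    "levene_test",
    "anova_oneway",
    "kruskal_wallis",
    "msa_orientation_test",
    "group_compare",
    "significance_tier",
]

ALPHA = 0.05


@dataclass
class ROISampleSet:
    """Per-group susceptibility samples (ppm) from one ROI.

    Groups are (label, values) pairs — orientations for anisotropy
    testing, cohorts (e.g. NC vs DA) for group comparison.
    """

    roi_name: str
    groups: List[Tuple[str, np.ndarray]]

    def __post_init__(self):
        if len(self.groups) < 2:
            raise ValidationError("need at least two groups")
        groups = []
        for label, values in self.groups:
            v = np.asarray(values, dtype=float).ravel()
            if v.size < 2:
                raise ValidationError(f"group {label!r} needs n >= 2")
            groups.append((str(label), v))
        self.groups = groups

    @property
    def value_arrays(self) -> List[np.ndarray]:
        return [v for _, v in self.groups]


@dataclass
class MSATestResult:
    """Outcome of the orientation-variation protocol for one ROI."""

    roi_name: str
    levene_p: float
    anova_p: float
    kw_p: float
    valid_test: str  # "ANOVA" or "KW"
    valid_p: float
    anisotropy_detected: bool

    def __post_init__(self):
        for name in ("levene_p", "anova_p", "kw_p", "valid_p"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} = {p} outside [0, 1]")
        expected = "ANOVA" if self.levene_p > ALPHA else "KW"
        if self.valid_test != expected:
            raise ValidationError("valid_test inconsistent with the Levene rule")


@dataclass
class GroupCompareResult:
    """Two-group t-test summary for one ROI."""

    roi_name: str
    group_stats: Dict[str, Tuple[float, float]]  # label -> (mean, sd)
    group_abs_means: Dict[str, float]
    percent_change: float
    t_p: float
    significance: str  # "", "*", or "**"


def _all_identical(groups: Sequence[np.ndarray]) -> bool:
    flat = np.concatenate(groups)
    return bool(np.all(flat == flat[0]))


def levene_test(groups: Sequence[np.ndarray]) -> float:
    """Median-centered Levene (Brown-Forsythe) p-value for equal variances."""
    groups = [np.asarray(g, float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValidationError("every group needs n >= 2")
    if all(np.ptp(g) == 0 for g in groups):
        return 1.0  # zero spread everywhere: variances trivially equal
    return float(stats.levene(*groups, center="median").pvalue)


def anova_oneway(groups: Sequence[np.ndarray]) -> float:
    """One-way ANOVA p-value; identical-data degenerate case -> p = 1."""
    groups = [np.asarray(g, float) for g in groups]
    if _all_identical(groups):
        return 1.0
    p = float(stats.f_oneway(*groups).pvalue)
    return 1.0 if np.isnan(p) else p


def kruskal_wallis(groups: Sequence[np.ndarray]) -> float:
    """Kruskal-Wallis H-test p-value; identical-data case -> p = 1."""
    groups = [np.asarray(g, float) for g in groups]
    if _all_identical(groups):
        return 1.0
    p = float(stats.kruskal(*groups).pvalue)
    return 1.0 if np.isnan(p) else p


def msa_orientation_test(roi_samples: ROISampleSet,
                         alpha: float = ALPHA) -> MSATestResult:
    """Run Levene + ANOVA + KW on per-orientation samples and select the
    valid omnibus test by the Levene rule (ANOVA iff levene_p > 0.05)."""
    groups = roi_samples.value_arrays
    if len(groups) < 2:
        raise ValidationError("orientation test needs >= 2 orientations")
    lev = levene_test(groups)
    an = anova_oneway(groups)
    kw = kruskal_wallis(groups)
    if lev > ALPHA:
        valid, valid_p = "ANOVA", an
    else:
        valid, valid_p = "KW", kw
    return MSATestResult(
        roi_name=roi_samples.roi_name,
        levene_p=lev, anova_p=an, kw_p=kw,
        valid_test=valid, valid_p=valid_p,
        anisotropy_detected=bool(valid_p < alpha),
    )


def significance_tier(p: float) -> str:
    """"**" for p < 0.01, "*" for 0.01 <= p < 0.05, else ""."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_compare(roi_samples: ROISampleSet, equal_var: bool = True,
                  bonferroni: int = 1) -> GroupCompareResult:
    """Two-sample t-test between exactly two groups (e.g. NC vs DA).

    Percent change is ``100 (mean_2 - mean_1) / |mean_1|`` with group 1
    the first (reference/control) group.  Absolute group means are
    reported alongside, since susceptibility levels are compared on
    magnitude.  ``bonferroni`` multiplies the p-value (capped at 1) for
    an optional correction across ROIs; default applies none.
    """
    if len(roi_samples.groups) != 2:
        raise ValidationError("group comparison needs exactly two groups")
    (lab1, g1), (lab2, g2) = roi_samples.groups
    if _all_identical([g1, g2]):
        p = 1.0
    else:
        p = float(stats.ttest_ind(g1, g2, equal_var=equal_var).pvalue)
    p = min(1.0, p * max(1, int(bonferroni)))
    m1, m2 = float(g1.mean()), float(g2.mean())
    if m1 == 0:
        raise ValidationError("reference group mean is zero; percent change undefined")
    return GroupCompareResult(
        roi_name=roi_samples.roi_name,
        group_stats={lab1: (m1, float(g1.std(ddof=1))),
                     lab2: (m2, float(g2.std(ddof=1)))},
        group_abs_means={lab1: abs(m1), lab2: abs(m2)},
        percent_change=100.0 * (m2 - m1) / abs(m1),
        t_p=p,
        significance=significance_tier(p),
    )
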