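"""Statistical analyses of cavity biometry.

Covers the study's toolbox: Cronbach's alpha for two-rater reliability,
Pearson correlation with t-distributed p-values, normality-gated two-sample
comparisons (Shapiro-Wilk, then Student's t with pooled variance; a
rank-sum statistic is reported alongside whenever normality is not
confirmed), cohort summary tables (mean +/- SD and range), and the
end-to-end inter-examiner reliability experiment on simulated raters.

Conventions: sample (n-1) variances, two-sided tests, significance 0.05,
raw-score (unstandardized) Cronbach's alpha, no multiple-testing
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RaterComparison",
    "CohortRecord",
    "GroupComparison",
    "cronbach_alpha",
    "pearson_correlation",
    "compare_groups",
    "cohort_summary",
    "reliability_experiment",
]


@dataclass
class RaterComparison:
    """Paired measurements of one quantity by two raters across eyes."""

    rater_a: np.ndarray
    rater_b: np.ndarray
    quantity: str = ""

    def __post_init__(self) -> None:
        self.rater_a = np.asarray(self.rater_a, dtype=float)
        self.rater_b = np.asarray(self.rater_b, dtype=float)
        if self.rater_a.shape != self.rater_b.shape or self.rater_a.ndim != 1:
            raise ValueError("rater vectors must be 1D and of equal length")
        if self.rater_a.size < 2:
            raise ValueError("need at least 2 paired measurements")


@dataclass
class CohortRecord:
    """One eye's clinical variables and cavity biometry."""

    eye_id: str
    age_years: float
    sex: str
    refractive_error_d: float
    axial_length_mm: float
    volumes_mm3: Dict[str, float]  # keys: whole, PMP, CC (subset ok)
    areas_mm2: Dict[str, float]
    connected_pmp_cc: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.axial_length_mm <= 0:
            raise ValueError("axial length must be positive")
        if "whole" not in self.volumes_mm3 or "whole" not in self.areas_mm2:
            raise ValueError("whole-cavity metrics are required")


def cronbach_alpha(comparison: RaterComparison) -> float:
    """Raw-score Cronbach's alpha for two raters.

    alpha = k/(k-1) * (1 - sum(var_i) / var_total), with k = 2 raters,
    sample variances, and var_total the variance of the per-eye sums.
    Perfect agreement gives 1; uncorrelated equal-variance raters give 0.
    """
    a, b = comparison.rater_a, comparison.rater_b
    var_a = float(np.var(a, ddof=1))
    var_b = float(np.var(b, ddof=1))
    var_tot = float(np.var(a + b, ddof=1))
    if var_tot == 0.0:
        raise ValueError(
            "total variance is zero: Cronbach's alpha is undefined for "
            "constant per-eye sums"
        )
    k = 2
    return k / (k - 1) * (1.0 - (var_a + var_b) / var_tot)


def pearson_correlation(x, y) -> Tuple[float, float]:
    """Product-moment r and two-sided p from the t-distribution (df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1D samples of size >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class GroupComparison:
    """Result of a normality-gated two-sample comparison."""

    statistic: float  # Student's t (pooled variance)
    p_value: float
    normality_confirmed: bool
    shapiro_p: Tuple[float, float]
    ranksum_statistic: Optional[float] = None
    ranksum_p: Optional[float] = None


def compare_groups(x, y, alpha: float = 0.05) -> GroupComparison:
    """Student's t test gated on Shapiro-Wilk normality of both groups.

    The pooled-variance t statistic and its p-value are always reported;
    if either group fails Shapiro-Wilk at ``alpha`` the result is flagged
    ``normality_confirmed=False`` and a Wilcoxon rank-sum test is reported
    alongside as the distribution-free alternative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x.mean() == y.mean():
        # degenerate identical-constant groups: no variance anywhere
        return GroupComparison(0.0, 1.0, True, (1.0, 1.0))
    sw_x = float(stats.shapiro(x).pvalue) if np.ptp(x) > 0 else 0.0
    sw_y = float(stats.shapiro(y).pvalue) if np.ptp(y) > 0 else 0.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    ok = sw_x >= alpha and sw_y >= alpha
    if ok:
        return GroupComparison(float(t), float(p), True, (sw_x, sw_y))
    u = stats.mannwhitneyu(x, y, alternative="two-sided")
    return GroupComparison(
        float(t), float(p), False, (sw_x, sw_y),
        ranksum_statistic=float(u.statistic), ranksum_p=float(u.pvalue),
    )


def cohort_summary(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Mean +/- SD and range table for clinical and biometric variables.

    A single record reports SD = 0 (the sample-SD convention with n = 1 is
    undefined; 0 is reported and documented). The sex tally is appended as
    a ``male/female`` row.
    """
    if not records:
        raise ValueError("cohort is empty")

    def col(getter) -> np.ndarray:
        return np.asarray([getter(r) for r in records], dtype=float)

    rows: List[Dict[str, object]] = []

    def add(name: str, values: np.ndarray) -> None:
        values = values[~np.isnan(values)]
        if values.size == 0:
            return
        sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
        rows.append(
            {
                "variable": name,
                "mean": float(values.mean()),
                "sd": sd,
                "min": float(values.min()),
                "max": float(values.max()),
                "n": int(values.size),
            }
        )

    add("age_years", col(lambda r: r.age_years))
    add("refractive_error_d", col(lambda r: r.refractive_error_d))
    add("axial_length_mm", col(lambda r: r.axial_length_mm))
    for s in ("whole", "PMP", "CC"):
        add(f"volume_{s}_mm3", col(lambda r, s=s: r.volumes_mm3.get(s, np.nan)))
    for s in ("whole", "PMP", "CC"):
        add(f"area_{s}_mm2", col(lambda r, s=s: r.areas_mm2.get(s, np.nan)))
    df = pd.DataFrame(rows)
    males = sum(1 for r in records if r.sex.lower().startswith("m"))
    df.attrs["sex_tally"] = f"{males}/{len(records) - males}"
    return df


# --------------------------------------------------------------------------
# end-to-end inter-examiner reliability on phantoms


def reliability_experiment(
    error_model_a,
    error_model_b,
    n_eyes: int = 6,
    seed: int = 0,
    segmenter: str = "fallback",
    grid_shape: Tuple[int, int, int] = (128, 96, 48),
    median_size: Tuple[int, int, int] = (5, 5, 5),
) -> Dict[str, object]:
    """Two simulated examiners label the same phantom eyes independently.

    For each of ``n_eyes`` phantoms (geometry varied eye-to-eye), the full
    pipeline — sparse labels on three planes, per-plane segmentation,
    majority fusion, median filtering, isotropic rescaling, volumetry —
    is run once per rater, and Cronbach's alpha of the paired whole-cavity
    volumes and surface areas is returned.
    """
    from .phantom import RaterErrorModel  # noqa: F401 (type reference)
    from .pipeline import PipelineConfig, phantom_cohort_specs, run_phantom_eye

    if n_eyes < 2:
        raise ValueError("reliability needs at least 2 eyes")
    specs = phantom_cohort_specs(n_eyes, seed=seed, grid_shape=grid_shape)
    vols_a, vols_b, areas_a, areas_b = [], [], [], []
    cfg = PipelineConfig(segmenter=segmenter, median_size=median_size)
    for i, spec in enumerate(specs):
        for model, vols, areas in (
            (error_model_a, vols_a, areas_a),
            (error_model_b, vols_b, areas_b),
        ):
            model_i = replace(model, seed=int(model.seed + 1000 * i + 1))
            try:
                metrics, _ = run_phantom_eye(spec, model_i, cfg)
            except Exception as exc:  # pragma: no cover - diagnostic path
                raise RuntimeError(f"pipeline failed on phantom eye {i}") from exc
            whole = metrics.get("whole")
            vols.append(whole.volume_mm3)
            areas.append(whole.area_mm2)

    alpha_v = cronbach_alpha(RaterComparison(np.array(vols_a), np.array(vols_b), "volume"))
    alpha_a = cronbach_alpha(RaterComparison(np.array(areas_a), np.array(areas_b), "area"))
    return {
        "alpha_volume": alpha_v,
        "alpha_area": alpha_a,
        "volumes_a": vols_a,
        "volumes_b": vols_b,
        "areas_a": areas_a,
        "areas_b": areas_b,
    }
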