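"""Statistical validation of colorimetric measurements.

One-way ANOVA (fixed-effects decomposition with an F test), Tukey HSD
pairwise comparisons, ISO 5725-style repeatability/reproducibility from a
one-factor nested design, Monte-Carlo propagation of RGB uncertainty into
the yellowness index, and the color-checker ΔE calibration summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .colorimetry import LabColor, delta_e_ab

__all__ = [
    "AnovaResult",
    "PrecisionReport",
    "one_way_anova",
    "tukey_hsd",
    "assumption_checks",
    "precision_metrics",
    "propagate_uncertainty",
    "calibration_report",
]


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    group_means: list[float]
    grand_mean: float
    ss_between: float
    ss_within: float

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.__dict__, **kwargs)


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical between/within sums-of-squares decomposition.

    The model is Y_ij = mu + tau_i + eps_ij with Gaussian errors; the F
    statistic is MS_between / MS_within with a p-value from the F
    distribution.  Zero within-group variance with unequal means is
    reported as F = inf, p = 0 instead of crashing.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least two observations")

    n = sum(a.size for a in arrs)
    k = len(arrs)
    grand = float(np.concatenate(arrs).mean())
    means = [float(a.mean()) for a in arrs]
    ss_between = float(sum(a.size * (m - grand) ** 2 for a, m in zip(arrs, means)))
    ss_within = float(sum(((a - m) ** 2).sum() for a, m in zip(arrs, means)))
    df_b, df_w = k - 1, n - k

    if ss_within == 0:
        if ss_between == 0:
            f, p = 0.0, 1.0
        else:
            f, p = float("inf"), 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        f_statistic=float(f),
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        group_means=means,
        grand_mean=grand,
        ss_between=ss_between,
        ss_within=ss_within,
    )


def tukey_hsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons with family-wise error control.

    Returns a DataFrame with one row per unordered pair: mean difference,
    adjusted p-value (studentized range) and a significance flag at
    ``alpha``.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    res = sps.tukey_hsd(*samples)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p = float(res.pvalue[i, j])
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(samples[i].mean() - samples[j].mean()),
                    "p_value": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def assumption_checks(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> dict:
    """Shapiro-Wilk normality per group and Levene homogeneity of variance."""
    out = {"normality": {}, "alpha": alpha}
    samples = [np.asarray(g, dtype=float) for g in groups.values()]
    for name, g in groups.items():
        w, p = sps.shapiro(np.asarray(g, dtype=float))
        out["normality"][name] = {"statistic": float(w), "p_value": float(p), "pass": p > alpha}
    stat, p = sps.levene(*samples)
    out["variance_homogeneity"] = {"statistic": float(stat), "p_value": float(p), "pass": p > alpha}
    return out


@dataclass
class PrecisionReport:
    repeatability_cv: float
    reproducibility_cv: float
    repeatability_sd: float
    reproducibility_sd: float
    between_session_sd: float
    grand_mean: float
    n_sessions: int
    reproducibility_defined: bool = True
    per_grade_sd: dict[str, float] = field(default_factory=dict)
    combined_uncertainty: dict[str, float] = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.__dict__, **kwargs)


def precision_metrics(replicates: Sequence[Sequence[float]] | Mapping[str, Sequence[float]]) -> PrecisionReport:
    """ISO 5725-2 one-factor precision decomposition.

    ``replicates`` holds measurements nested by session (or operator/day):
    one inner sequence per session.  Repeatability variance s_r^2 is the
    pooled within-session variance; the between-session component s_L^2 is
    (MS_between - MS_within)/n_bar (clipped at zero); reproducibility
    variance is s_R^2 = s_r^2 + s_L^2.  CVs divide by the grand mean.

    A single session leaves reproducibility undefined (flagged, set equal
    to repeatability).
    """
    if isinstance(replicates, Mapping):
        cells = [np.asarray(v, dtype=float) for v in replicates.values()]
    else:
        cells = [np.asarray(v, dtype=float) for v in replicates]
    if not cells:
        raise ValueError("no replicate data")
    if any(c.size < 2 for c in cells):
        raise ValueError("each session needs at least two replicates")

    grand = float(np.concatenate(cells).mean())
    ms_within = float(np.mean([c.var(ddof=1) for c in cells]))
    s_r = np.sqrt(ms_within)

    if len(cells) < 2:
        return PrecisionReport(
            repeatability_cv=s_r / abs(grand) if grand else float("nan"),
            reproducibility_cv=float("nan"),
            repeatability_sd=float(s_r),
            reproducibility_sd=float("nan"),
            between_session_sd=float("nan"),
            grand_mean=grand,
            n_sessions=1,
            reproducibility_defined=False,
        )

    n_bar = float(np.mean([c.size for c in cells]))
    ms_between = n_bar * float(np.var([c.mean() for c in cells], ddof=1))
    s_l_sq = max(0.0, (ms_between - ms_within) / n_bar)
    s_R = np.sqrt(ms_within + s_l_sq)
    return PrecisionReport(
        repeatability_cv=float(s_r / abs(grand)) if grand else float("nan"),
        reproducibility_cv=float(s_R / abs(grand)) if grand else float("nan"),
        repeatability_sd=float(s_r),
        reproducibility_sd=float(s_R),
        between_session_sd=float(np.sqrt(s_l_sq)),
        grand_mean=grand,
        n_sessions=len(cells),
    )


def propagate_uncertainty(
    rgb_mean: Sequence[float],
    rgb_sd: Sequence[float],
    n_mc: int = 100_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo standard uncertainty of the yellowness index.

    RGB triples are drawn from independent normals, clipped to the 8-bit
    range, pushed through the table-consistent YI path, and the sample SD
    of the resulting YI returned.
    """
    mean = np.asarray(rgb_mean, dtype=float)
    sd = np.asarray(rgb_sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("rgb_sd must be non-negative")
    if n_mc < 1000:
        raise ValueError("n_mc must be at least 1000")
    if np.all(sd == 0):
        return 0.0
    rng = np.random.default_rng(seed)
    draws = np.clip(rng.normal(mean, sd, size=(n_mc, 3)), 0.0, 255.0)
    # YI only needs the raw-linear matrix transform, so vectorize it.
    from .colorimetry import SRGB_D65_MATRIX, YellownessConfig

    cx, cz = YellownessConfig().coefficients()
    xyz = draws @ SRGB_D65_MATRIX.T
    yi = 100.0 * (cx * xyz[:, 0] - cz * xyz[:, 2]) / xyz[:, 1]
    return float(np.std(yi, ddof=1))


def calibration_report(
    measured: Sequence[LabColor],
    reference: Sequence[LabColor],
    tolerance: float = 2.0,
) -> dict:
    """Per-patch CIE76 ΔE against certified references plus summary stats."""
    if len(measured) != len(reference):
        raise ValueError(
            f"patch count mismatch: {len(measured)} measured vs {len(reference)} reference"
        )
    de = np.array([delta_e_ab(m, r) for m, r in zip(measured, reference)])
    return {
        "per_patch_delta_e": de.tolist(),
        "mean": float(de.mean()),
        "sd": float(de.std(ddof=1)) if de.size > 1 else 0.0,
        "max": float(de.max()),
        "tolerance": tolerance,
        "pass_fraction": float((de <= tolerance).mean()),
        "n_patches": int(de.size),
    }
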