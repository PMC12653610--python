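"""Threshold calibration and hierarchical decision-tree grade assignment.

Grading uses a fixed-order decision tree over the colorimetric summary
(YI on the table-consistent raw path; L* and a* from the linearized CIELAB
path):

1. YI < 9.5            -> white crepe (premium, near-achromatic)
2. else YI < 31        -> RSS5 (dark sheet: low lightness suppresses YI)
3. else 20 < L* < 36.4 -> RSS3 (high-YI smoked sheet, low lightness)
4. else a* < -0.5      -> STR5L (greenish undertone)
5. else                -> STR5

All comparisons are strict ``<`` and at most five are evaluated per
specimen.  The lightness test must precede the a* split: RSS3 has a
strongly positive a* (red component) and a YI range overlapping the STR
grades, so it can only be routed by lightness.  The published L* > 20
bound is kept as a guard separating RSS3 from extreme dark outliers.

Calibration computes per-grade mean +/- 2 SD acceptance ranges for each
colorimetric parameter from labeled training vectors; vectors far outside
every grade's ranges are reported as ``unclassified`` rather than silently
assigned the residual grade.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .colorimetry import ColorVector

__all__ = ["Grade", "GradeModel", "GradeDecision", "calibrate", "assign_grade"]


class Grade(str, enum.Enum):
    WHITE_CREPE = "white_crepe"
    STR5 = "STR5"
    STR5L = "STR5L"
    RSS3 = "RSS3"
    RSS5 = "RSS5"
    UNCLASSIFIED = "unclassified"


_PARAMS = ("yi", "l_star", "a_star", "b_star")


@dataclass
class GradeModel:
    """Decision-tree split points plus optional per-grade acceptance ranges.

    ``per_grade_ranges`` maps grade -> parameter -> (low, high) intervals
    (mean +/- 2 SD of training data).  ``outlier_margin_sd`` widens those
    intervals (in SD units) before a vector is declared unclassified; with
    no calibrated ranges the outlier check is skipped.
    """

    yi_white_crepe_max: float = 9.5
    yi_rss5_max: float = 31.0
    a_star_split: float = -0.5
    l_star_rss3_max: float = 36.4
    l_star_outlier_min: float = 20.0
    per_grade_ranges: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    per_grade_sd: dict[str, dict[str, float]] = field(default_factory=dict)
    outlier_margin_sd: float = 2.0

    def __post_init__(self) -> None:
        if not self.yi_white_crepe_max < self.yi_rss5_max:
            raise ValueError("yi_white_crepe_max must be below yi_rss5_max")
        for grade, ranges in self.per_grade_ranges.items():
            for p, (lo, hi) in ranges.items():
                if lo > hi:
                    raise ValueError(f"invalid interval for {grade}/{p}: ({lo}, {hi})")

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.__dict__, **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GradeModel":
        d = dict(d)
        d["per_grade_ranges"] = {
            g: {p: tuple(v) for p, v in r.items()}
            for g, r in d.get("per_grade_ranges", {}).items()
        }
        return cls(**d)


@dataclass
class GradeDecision:
    grade: Grade
    comparisons_used: int
    trace: list[tuple[str, float, bool]]

    def __post_init__(self) -> None:
        assert self.comparisons_used <= 5, "decision tree exceeded five comparisons"


def _params_of(v: ColorVector | Mapping[str, float]) -> dict[str, float]:
    if isinstance(v, ColorVector):
        return {
            "yi": v.yi,
            "l_star": v.lab.L_star,
            "a_star": v.lab.a_star,
            "b_star": v.lab.b_star,
        }
    missing = [k for k in _PARAMS if k not in v]
    if missing:
        raise ValueError(f"color vector missing components: {missing}")
    return {k: float(v[k]) for k in _PARAMS}


def calibrate(
    training: Iterable[tuple[ColorVector | Mapping[str, float], str | Grade]],
    **model_kwargs,
) -> GradeModel:
    """Per-grade mean +/- 2 SD acceptance ranges from labeled vectors.

    Requires at least two specimens per represented grade (sample SD with
    ddof=1).  Tree split points keep their documented defaults unless
    overridden through ``model_kwargs``.
    """
    by_grade: dict[str, list[dict[str, float]]] = {}
    for v, label in training:
        by_grade.setdefault(Grade(label).value, []).append(_params_of(v))

    ranges: dict[str, dict[str, tuple[float, float]]] = {}
    sds: dict[str, dict[str, float]] = {}
    for grade, rows in by_grade.items():
        if len(rows) < 2:
            raise ValueError(
                f"grade {grade!r} has {len(rows)} specimen(s); need >= 2 to calibrate"
            )
        ranges[grade] = {}
        sds[grade] = {}
        for p in _PARAMS:
            vals = np.array([r[p] for r in rows])
            mu, sd = float(vals.mean()), float(vals.std(ddof=1))
            ranges[grade][p] = (mu - 2 * sd, mu + 2 * sd)
            sds[grade][p] = sd
    return GradeModel(per_grade_ranges=ranges, per_grade_sd=sds, **model_kwargs)


def _in_expanded_range(x: float, lo: float, hi: float, sd: float, margin: float) -> bool:
    return (lo - margin * sd) <= x <= (hi + margin * sd)


def assign_grade(v: ColorVector | Mapping[str, float], m: GradeModel | None = None) -> GradeDecision:
    """Route a colorimetric vector through the hierarchical decision tree."""
    if m is None:
        m = GradeModel()
    p = _params_of(v)
    trace: list[tuple[str, float, bool]] = []

    def test(rule: str, value: float, outcome: bool) -> bool:
        trace.append((rule, value, outcome))
        return outcome

    if test(f"YI < {m.yi_white_crepe_max}", p["yi"], p["yi"] < m.yi_white_crepe_max):
        grade = Grade.WHITE_CREPE
    elif test(f"YI < {m.yi_rss5_max}", p["yi"], p["yi"] < m.yi_rss5_max):
        grade = Grade.RSS5
    elif test(f"L* < {m.l_star_rss3_max}", p["l_star"], p["l_star"] < m.l_star_rss3_max) and test(
        f"L* > {m.l_star_outlier_min}", p["l_star"], p["l_star"] > m.l_star_outlier_min
    ):
        grade = Grade.RSS3
    elif test(f"a* < {m.a_star_split}", p["a_star"], p["a_star"] < m.a_star_split):
        grade = Grade.STR5L
    else:
        grade = Grade.STR5

    # Outlier guard: a vector far outside every calibrated grade range is
    # flagged rather than silently landing in a residual leaf.
    if m.per_grade_ranges:
        near_any = False
        for g, ranges in m.per_grade_ranges.items():
            sds = m.per_grade_sd.get(g, {})
            if all(
                _in_expanded_range(p[par], *ranges[par], sds.get(par, 0.0), m.outlier_margin_sd)
                for par in ranges
            ):
                near_any = True
                break
        if not near_any:
            grade = Grade.UNCLASSIFIED

    return GradeDecision(grade=grade, comparisons_used=len(trace), trace=trace)
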