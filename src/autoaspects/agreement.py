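"""Agreement statistics between raters of ASPECTS region status.

Implements every statistic used to validate automated ASPECTS against a
reference standard: region-level confusion counts and rounded percentage
metrics, trichotomized score agreement (bands 0-4 / 5-7 / 8-10),
intraclass correlation ICC(1,1) (one-way random effects, absolute
agreement, single rater) with its F-based 95% confidence interval, and
Bland-Altman limits of agreement.

Percentages are rounded half away from zero to integers, matching the
convention of clinical reporting (e.g. 711/798 -> 89%, 353/622 -> 57%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, SpecificationError
from .regions import ALL_REGIONS, Region

TRICHOTOMY_BANDS = ((0, 4, "low"), (5, 7, "mid"), (8, 10, "high"))


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise SpecificationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity_pct(self) -> int:
        return round_half_away(100.0 * self.tp / (self.tp + self.fn))

    @property
    def specificity_pct(self) -> int:
        return round_half_away(100.0 * self.tn / (self.tn + self.fp))

    @property
    def accuracy_pct(self) -> int:
        return round_half_away(100.0 * (self.tp + self.tn) / self.total)


class RatingTable:
    """Per-patient binary region ratings for one rater.

    Wraps a patients x 10 DataFrame of {0, 1} (1 = affected), indexed by
    patient id with one column per ASPECTS region. The derived per-patient
    ASPECTS is 10 minus the number of affected regions.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [r.value for r in ALL_REGIONS if r.value not in data.columns]
        if missing:
            raise SpecificationError(f"rating table missing region columns {missing}")
        data = data[[r.value for r in ALL_REGIONS]].copy()
        values = data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise SpecificationError("rating cells must be 0 (normal) or 1 (affected)")
        self.data = data.astype(int)

    @property
    def patients(self) -> pd.Index:
        return self.data.index

    @property
    def scores(self) -> pd.Series:
        """Derived ASPECTS per patient: 10 - number of affected regions."""
        return 10 - self.data.sum(axis=1)

    @classmethod
    def from_csv(cls, path) -> "RatingTable":
        df = pd.read_csv(path)
        if "patient_id" not in df.columns:
            raise SpecificationError("rating CSV needs a patient_id column")
        return cls(df.set_index("patient_id"))

    def to_csv(self, path) -> None:
        self.data.rename_axis("patient_id").to_csv(path)


def _align(pred: RatingTable, ref: RatingTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    if set(pred.patients) != set(ref.patients):
        raise AlignmentError("rating tables cover different patients")
    order = sorted(pred.patients)
    return pred.data.loc[order], ref.data.loc[order]


def confusion(
    pred: RatingTable,
    ref: RatingTable,
    regions: tuple[Region, ...] = ALL_REGIONS,
) -> ConfusionCounts:
    """Cell-wise confusion counts over the selected regions.

    "Affected" (1) is the positive class; ``ref`` is the reference standard.
    """
    p, r = _align(pred, ref)
    cols = [reg.value for reg in regions]
    pv = p[cols].to_numpy().ravel()
    rv = r[cols].to_numpy().ravel()
    return ConfusionCounts(
        tp=int(((pv == 1) & (rv == 1)).sum()),
        tn=int(((pv == 0) & (rv == 0)).sum()),
        fp=int(((pv == 1) & (rv == 0)).sum()),
        fn=int(((pv == 0) & (rv == 1)).sum()),
    )


def trichotomize(score: int) -> str:
    """Band an ASPECTS into low (0-4), mid (5-7), or high (8-10)."""
    if not (isinstance(score, (int, np.integer)) and 0 <= score <= 10):
        raise SpecificationError(f"ASPECTS must be an integer in 0..10, got {score!r}")
    for lo, hi, band in TRICHOTOMY_BANDS:
        if lo <= score <= hi:
            return band
    raise AssertionError("unreachable")


def icc_1_1(scores: np.ndarray) -> tuple[float, tuple[float, float]]:
    """ICC(1,1): one-way random effects, absolute agreement, single rater.

    ``scores`` is an (n targets x k raters) array. From the one-way ANOVA
    mean squares MSB (between targets) and MSW (within targets),

        ICC = (MSB - MSW) / (MSB + (k - 1) * MSW)

    with a 95% CI from F-distribution bounds on MSB/MSW
    (FL = F / F_{0.975; n-1, n(k-1)}, FU = F * F_{0.975; n(k-1), n-1};
    bound = (FL - 1)/(FL + k - 1) etc.). Raises on zero total variance.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise SpecificationError("scores must be a 2D (targets x raters) array")
    n, k = scores.shape
    if n < 3 or k < 2:
        raise SpecificationError("ICC(1,1) needs >= 3 targets and >= 2 ratings each")
    if np.ptp(scores) == 0:
        raise SpecificationError("degenerate input: zero total variance")

    grand = scores.mean()
    row_means = scores.mean(axis=1)
    ss_between = k * float(((row_means - grand) ** 2).sum())
    ss_within = float(((scores - row_means[:, None]) ** 2).sum())
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    if msw == 0 and msb == 0:
        raise SpecificationError("degenerate input: zero total variance")
    icc = (msb - msw) / (msb + (k - 1) * msw)

    if msw == 0:
        return icc, (icc, icc)
    f = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    fl = f / stats.f.ppf(0.975, df1, df2)
    fu = f * stats.f.ppf(0.975, df2, df1)
    lower = (fl - 1) / (fl + k - 1)
    upper = (fu - 1) / (fu + k - 1)
    return float(icc), (float(lower), float(upper))


def bland_altman(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Bland-Altman summary of paired scores: (mean difference, lower and
    upper 95% limits of agreement, mean +/- 1.96 * SD with SD on n-1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise AlignmentError("paired score vectors of equal length >= 2 required")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


@dataclass(frozen=True)
class AgreementReport:
    counts: ConfusionCounts
    sensitivity_pct: int
    specificity_pct: int
    accuracy_pct: int
    trichotomized_agreeing: int
    trichotomized_total: int
    trichotomized_pct: int
    icc: float
    icc_ci: tuple[float, float]
    bland_altman: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {
            "counts": {
                "tp": self.counts.tp,
                "tn": self.counts.tn,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
            },
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "accuracy_pct": self.accuracy_pct,
            "trichotomized": {
                "agreeing": self.trichotomized_agreeing,
                "total": self.trichotomized_total,
                "pct": self.trichotomized_pct,
            },
            "icc": round(self.icc, 4),
            "icc_ci": [round(v, 4) for v in self.icc_ci],
            "bland_altman": {
                "mean_diff": round(self.bland_altman[0], 4),
                "loa_low": round(self.bland_altman[1], 4),
                "loa_high": round(self.bland_altman[2], 4),
            },
        }


def trichotomized_agreement(
    scores_a: pd.Series, scores_b: pd.Series
) -> tuple[int, int, int]:
    """(agreeing patients, total, rounded percent) of banded score agreement."""
    if len(scores_a) != len(scores_b):
        raise AlignmentError("score vectors differ in length")
    bands_a = [trichotomize(int(s)) for s in scores_a]
    bands_b = [trichotomize(int(s)) for s in scores_b]
    agreeing = sum(x == y for x, y in zip(bands_a, bands_b))
    total = len(bands_a)
    return agreeing, total, round_half_away(100.0 * agreeing / total)


def full_report(pred: RatingTable, ref: RatingTable) -> AgreementReport:
    """Assemble the complete agreement report between two rating tables.

    Confusion over all 10 regions with rounded percent metrics,
    trichotomized per-patient score agreement, ICC(1,1) on the derived
    ASPECTS, and Bland-Altman (pred - ref) on the derived ASPECTS.
    """
    counts = confusion(pred, ref)
    order = sorted(pred.patients)
    scores_pred = pred.scores.loc[order]
    scores_ref = ref.scores.loc[order]
    agreeing, total, pct = trichotomized_agreement(scores_pred, scores_ref)
    if scores_pred.equals(scores_ref):
        icc, ci = 1.0, (1.0, 1.0)
        ba = (0.0, 0.0, 0.0)
    else:
        icc, ci = icc_1_1(np.column_stack([scores_pred, scores_ref]))
        ba = bland_altman(scores_pred.to_numpy(), scores_ref.to_numpy())
    return AgreementReport(
        counts=counts,
        sensitivity_pct=counts.sensitivity_pct,
        specificity_pct=counts.specificity_pct,
        accuracy_pct=counts.accuracy_pct,
        trichotomized_agreeing=agreeing,
        trichotomized_total=total,
        trichotomized_pct=pct,
        icc=icc,
        icc_ci=ci,
        bland_altman=ba,
    )
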