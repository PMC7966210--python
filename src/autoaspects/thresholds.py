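"""Threshold training: stratified splitting, ROC curves, and selection of a
relative-difference threshold under a specificity floor.

Observations are region-level: one row per (patient, region) with the
measured relative HU difference and a binary reference status
(affected / normal). Classification follows the scorer's rule: a region is
called affected when its relative difference is >= the threshold. Training
selects, among candidate thresholds (the observed values themselves plus
sentinels), the one with maximal sensitivity subject to
specificity >= a floor (default 0.90) on the training data.

Patients — never individual regions — are the sampling unit for both the
train/test split and the bootstrap used for AUC confidence intervals,
because the 10 regions of one patient are correlated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InfeasibleThresholdError, SpecificationError
from .regions import CENTRAL_REGIONS, CORTICAL_REGIONS, Region
from .scorer import ThresholdSet

logger = logging.getLogger(__name__)

#: required columns of an observations table
OBS_COLUMNS = ("patient_id", "region", "diff_pct", "reference")


def _check_observations(obs: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise SpecificationError(f"observations table missing columns {missing}")
    if obs.duplicated(subset=["patient_id", "region"]).any():
        raise SpecificationError("duplicate (patient, region) observation")
    return obs


@dataclass(frozen=True)
class RocCurve:
    """ROC over candidate thresholds with rule `diff >= t -> affected`."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float] | None


def stratified_split(
    obs: pd.DataFrame,
    train_fraction: float,
    strata: pd.Series | None = None,
    seed: int = 0,
) -> tuple[set, set]:
    """Split patients (never regions) into train/test sets, per stratum.

    ``strata`` maps patient_id -> stratum label; None puts every patient in
    one stratum. Within each stratum the number of training patients is the
    rounded target fraction, so the realized fraction deviates from the
    target by at most one patient per stratum. A single-patient stratum is
    assigned wholly to one side (with a warning), so the overall fraction
    can drift from the target — the price of stratification.
    """
    if not 0.0 < train_fraction < 1.0:
        raise SpecificationError("train_fraction must be in (0, 1)")
    _check_observations(obs)
    patients = pd.Index(sorted(obs["patient_id"].unique()))
    if strata is None:
        strata = pd.Series("all", index=patients)
    else:
        strata = strata.reindex(patients)
        if strata.isna().any():
            raise SpecificationError("every patient needs a stratum label")

    rng = np.random.default_rng(seed)
    train: set = set()
    test: set = set()
    for stratum in sorted(strata.unique()):
        members = list(strata.index[strata == stratum])
        if len(members) == 1:
            # cannot split a singleton; send it to the majority side
            side = train if train_fraction >= 0.5 else test
            side.add(members[0])
            warnings.warn(
                f"stratum {stratum!r} has a single patient; assigned wholly "
                "to one side",
                stacklevel=2,
            )
            continue
        order = rng.permutation(len(members))
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 0), len(members))
        for rank, i in enumerate(order):
            (train if rank < n_train else test).add(members[i])
    return train, test


def _confusion_at(diffs: np.ndarray, labels: np.ndarray, threshold: float):
    """(sensitivity, specificity) of rule diff >= threshold."""
    pred = diffs >= threshold
    pos = labels == 1
    tp = int((pred & pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    fp = int((pred & ~pos).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def _auc_midrank(diffs: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann–Whitney rank statistic with midranks for ties."""
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise SpecificationError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(diffs)  # midranks
    rank_sum_pos = float(ranks[pos].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def roc(
    obs: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> RocCurve:
    """ROC curve, AUC (midrank Mann–Whitney), and bootstrap AUC CI.

    Candidate thresholds are the distinct observed differences plus -inf and
    +inf sentinels. The CI resamples patients (cluster bootstrap) with
    ``n_boot`` replicates; pass ``n_boot=0`` to skip it.
    """
    _check_observations(obs)
    diffs = obs["diff_pct"].to_numpy(dtype=float)
    labels = obs["reference"].to_numpy(dtype=int)

    candidates = np.concatenate(([-np.inf], np.unique(diffs), [np.inf]))
    sens = np.empty(candidates.size)
    spec = np.empty(candidates.size)
    for i, t in enumerate(candidates):
        sens[i], spec[i] = _confusion_at(diffs, labels, t)
    auc = _auc_midrank(diffs, labels)

    auc_ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        groups = obs.groupby("patient_id", sort=True)
        patient_ids = np.array(sorted(groups.groups))
        by_patient = [
            (
                groups.get_group(pid)["diff_pct"].to_numpy(dtype=float),
                groups.get_group(pid)["reference"].to_numpy(dtype=int),
            )
            for pid in patient_ids
        ]
        boot = np.empty(n_boot)
        n_pat = len(by_patient)
        for b in range(n_boot):
            take = rng.integers(0, n_pat, size=n_pat)
            d = np.concatenate([by_patient[i][0] for i in take])
            y = np.concatenate([by_patient[i][1] for i in take])
            if y.min() == y.max():  # degenerate resample
                boot[b] = np.nan
                continue
            boot[b] = _auc_midrank(d, y)
        alpha = 1.0 - ci_level
        lo, hi = np.nanpercentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        auc_ci = (min(float(lo), auc), max(float(hi), auc))

    return RocCurve(
        thresholds=candidates,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=auc_ci,
    )


def optimize_threshold(obs: pd.DataFrame, min_specificity: float = 0.90) -> float:
    """Best threshold under a specificity floor.

    Among candidate thresholds (the distinct observed differences; the
    infinite sentinels are excluded because "classify nothing" is not a
    usable operating point) with training specificity >= ``min_specificity``,
    return the one maximizing sensitivity; ties broken by higher
    specificity, then by smaller threshold. Raises InfeasibleThresholdError
    (reporting the maximum achievable specificity) when no candidate meets
    the floor.
    """
    _check_observations(obs)
    diffs = obs["diff_pct"].to_numpy(dtype=float)
    labels = obs["reference"].to_numpy(dtype=int)
    if labels.min() == labels.max():
        raise SpecificationError("threshold optimization needs both classes")

    candidates = np.unique(diffs)
    best = None  # (sens, spec, -threshold)
    best_threshold = None
    max_spec = 0.0
    for t in candidates:
        sens, spec = _confusion_at(diffs, labels, t)
        max_spec = max(max_spec, spec)
        if spec < min_specificity:
            continue
        key = (sens, spec, -t)
        if best is None or key > best:
            best = key
            best_threshold = float(t)
    if best_threshold is None:
        raise InfeasibleThresholdError(min_specificity, max_spec)
    return best_threshold


def fit_grouped_thresholds(
    obs: pd.DataFrame, min_specificity: float = 0.90, mode: str = "grouped"
) -> ThresholdSet:
    """Fit detection thresholds on training observations.

    ``grouped``: one threshold for the central regions (CN, IC, INS, LN) and
    one for the cortical regions (M1–M6), each optimized separately.
    ``single``: one threshold pooled over all 10 regions.
    """
    _check_observations(obs)
    region = obs["region"].map(lambda r: Region(r))
    if mode == "grouped":
        central = obs[region.isin(CENTRAL_REGIONS)]
        cortical = obs[region.isin(CORTICAL_REGIONS)]
        central_t = optimize_threshold(central, min_specificity)
        cortical_t = optimize_threshold(cortical, min_specificity)
        logger.info("fitted grouped thresholds: central=%.4g cortical=%.4g", central_t, cortical_t)
        return ThresholdSet(mode="grouped", central_pct=central_t, cortical_pct=cortical_t)
    if mode == "single":
        single_t = optimize_threshold(obs, min_specificity)
        logger.info("fitted single threshold: %.4g", single_t)
        return ThresholdSet(mode="single", single_pct=single_t)
    raise SpecificationError(f"unknown threshold-fit mode {mode!r}")


def evaluate_thresholds(obs: pd.DataFrame, thresholds: ThresholdSet) -> dict:
    """Sensitivity/specificity/confusion of a ThresholdSet on observations."""
    _check_observations(obs)
    diffs = obs["diff_pct"].to_numpy(dtype=float)
    labels = obs["reference"].to_numpy(dtype=int)
    thr = obs["region"].map(lambda r: thresholds.for_region(Region(r))).to_numpy(dtype=float)
    pred = diffs >= thr
    pos = labels == 1
    tp = int((pred & pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    fp = int((pred & ~pos).sum())
    return {
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": (tp + tn) / len(labels) if len(labels) else float("nan"),
    }
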