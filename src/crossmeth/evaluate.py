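"""Cross-validation harness, accuracy metrics and diagnostic summaries.

Prediction accuracy is summarized two ways, both as the squared Pearson
correlation R² (the field's convention for agreement between beta vectors --
note this differs from 1 - SSE/SST for biased predictions) together with the
mean absolute error MAE:

* per sample: true vs predicted target methylation across probes;
* per probe: true vs predicted target methylation across samples, alongside
  the target-tissue standard deviation of the probe (accuracy is expected to
  track variability).

Cross-validation holds out one sample -- or one whole family, so that
related individuals never span the train/test split -- per fold, fits the
calibration models on the remaining samples only, and assembles a full
predicted matrix from the held-out predictions. Metrics use
pairwise-complete data; probes or samples that fail minimum-data rules are
reported as missing with a reason rather than silently excluded.

Also here: the raw cross-tissue correlation summary (per-sample R² between
tissues under successive extreme-probe filters), the accuracy-by-variability
stratification, the density-by-bin diagnostic (how often raw surrogate
values and calibrated predictions fall inside the decile window of the true
target value), and the training-sample-size experiment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import BetaMatrix, SampleMetadata, ValidationError
from .predict import (
    PredictionResult,
    fit_multiprobe,
    fit_probe_models,
    predict_matrix,
    predict_multiprobe,
)
from .preprocess import DEFAULT_EXTREME_FILTERS, ExtremeProbeFilter, filter_extreme_probes

logger = logging.getLogger(__name__)

#: Training-set sizes examined in the sample-size experiment.
DEFAULT_SAMPLE_SIZES = (3, 4, 5, 6, 7, 8, 10, 20, 30, 39)

#: Below this training size a warning is emitted; at least 10 training
#: samples are recommended.
RECOMMENDED_MIN_TRAIN = 10

__all__ = [
    "CvScheme",
    "AccuracyReport",
    "BinDensitySummary",
    "sample_r2",
    "sample_mae",
    "probe_r2",
    "probe_mae",
    "cross_validate",
    "cross_tissue_correlation",
    "accuracy_by_variability",
    "density_by_bin",
    "sample_size_experiment",
    "DEFAULT_SAMPLE_SIZES",
]


@dataclass
class CvScheme:
    """Cross-validation fold structure.

    ``mode`` is ``"family"`` (leave-one-family-out; requires a family map) or
    ``"sample"`` (leave-one-sample-out). Folds partition the samples.
    """

    mode: str
    family_map: dict | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("family", "sample"):
            raise ValidationError(f"unknown CV mode {self.mode!r}")
        if self.mode == "family" and not self.family_map:
            raise ValidationError("family mode requires a family map")

    @classmethod
    def from_metadata(cls, meta: SampleMetadata, mode: str = "family") -> "CvScheme":
        return cls(mode=mode, family_map=meta.family_map())

    def folds(self, sample_ids: Sequence) -> list:
        if self.mode == "sample":
            return [[s] for s in sample_ids]
        missing = [s for s in sample_ids if s not in self.family_map]
        if missing:
            raise ValidationError(f"samples without a family id: {missing[:5]}")
        by_family: dict = {}
        for s in sample_ids:
            by_family.setdefault(self.family_map[s], []).append(s)
        return [by_family[f] for f in sorted(by_family)]


def _pairwise(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    return a[ok], b[ok]


def _r2_with_reason(true_vec, pred_vec) -> tuple[float, str]:
    t, p = _pairwise(true_vec, pred_vec)
    if t.size < 3:
        return np.nan, "fewer than 3 pairs"
    if t.std() == 0 or p.std() == 0:
        return np.nan, "constant vector"
    r = np.corrcoef(t, p)[0, 1]
    return float(r * r), ""


def sample_r2(true_row, pred_row) -> float:
    """Squared Pearson correlation over pairwise-complete entries.

    Undefined (NaN) for constant vectors or fewer than three pairs.
    """
    return _r2_with_reason(true_row, pred_row)[0]


def sample_mae(true_row, pred_row) -> float:
    """Mean absolute error over pairwise-complete entries."""
    t, p = _pairwise(true_row, pred_row)
    if t.size < 1:
        return np.nan
    return float(np.mean(np.abs(t - p)))


# Per-probe metrics are the same computations with sample/probe roles
# transposed; exposed under their own names for call-site clarity.
probe_r2 = sample_r2
probe_mae = sample_mae


@dataclass
class AccuracyReport:
    """Per-sample and per-probe accuracy of a predicted matrix.

    ``per_sample`` columns: r2, mae, n_pairs, reason.
    ``per_probe`` columns: r2, mae, sd_target, n_pairs, reason.
    ``overall`` holds nan-mean summaries of both views.
    """

    per_sample: pd.DataFrame
    per_probe: pd.DataFrame
    overall: dict
    method: str
    n_out_of_range: int
    n_folds: int = 0


def _build_report(Y: BetaMatrix, pred: pd.DataFrame, method: str, n_oor: int, n_folds: int) -> AccuracyReport:
    rows = []
    for s in Y.sample_ids:
        r2, reason = _r2_with_reason(Y.data.loc[s], pred.loc[s])
        mae = sample_mae(Y.data.loc[s], pred.loc[s])
        n = int((~Y.data.loc[s].isna() & ~pred.loc[s].isna()).sum())
        rows.append((s, r2, mae, n, reason))
    per_sample = pd.DataFrame(
        rows, columns=["sample_id", "r2", "mae", "n_pairs", "reason"]
    ).set_index("sample_id")
    rows = []
    sd_target = np.nanstd(Y.values, axis=0, ddof=1)
    for j, p in enumerate(Y.probe_ids):
        r2, reason = _r2_with_reason(Y.data[p], pred[p])
        mae = probe_mae(Y.data[p], pred[p])
        n = int((~Y.data[p].isna() & ~pred[p].isna()).sum())
        rows.append((p, r2, mae, sd_target[j], n, reason))
    per_probe = pd.DataFrame(
        rows, columns=["probe_id", "r2", "mae", "sd_target", "n_pairs", "reason"]
    ).set_index("probe_id")
    overall = {
        "mean_sample_r2": float(np.nanmean(per_sample["r2"])) if per_sample["r2"].notna().any() else np.nan,
        "mean_sample_mae": float(np.nanmean(per_sample["mae"])) if per_sample["mae"].notna().any() else np.nan,
        "mean_probe_r2": float(np.nanmean(per_probe["r2"])) if per_probe["r2"].notna().any() else np.nan,
        "mean_probe_mae": float(np.nanmean(per_probe["mae"])) if per_probe["mae"].notna().any() else np.nan,
    }
    return AccuracyReport(
        per_sample=per_sample,
        per_probe=per_probe,
        overall=overall,
        method=method,
        n_out_of_range=n_oor,
        n_folds=n_folds,
    )


def cross_validate(
    X: BetaMatrix,
    Y: BetaMatrix,
    scheme: CvScheme,
    method: str = "LM",
    k: int = 5,
    target_probes: Sequence | None = None,
    epsilon: float = 0.1,
    cost: float = 1.0,
) -> tuple[PredictionResult, AccuracyReport]:
    """Leakage-free cross-validated prediction of the target tissue.

    Per fold, models are fitted on the training partition only and applied to
    the held-out samples; a held-out sample's own data never influences its
    prediction. ``method`` is ``"LM"``, ``"SVR"`` or ``"multiprobe-LM"``
    (with ``k`` predictors, optionally restricted to ``target_probes``).
    """
    if X.sample_ids != Y.sample_ids or X.probe_ids != Y.probe_ids:
        raise ValidationError("X and Y must be aligned (same samples and probes, same order)")
    folds = scheme.folds(X.sample_ids)
    if len(folds) < 2:
        raise ValidationError("cross-validation needs at least 2 folds")
    if target_probes is None:
        out_probes = X.probe_ids
    else:
        out_probes = list(target_probes)
    pred = pd.DataFrame(np.nan, index=X.sample_ids, columns=out_probes)
    n_oor = 0
    for fold in folds:
        held = set(fold)
        train_ids = [s for s in X.sample_ids if s not in held]
        if len(train_ids) < RECOMMENDED_MIN_TRAIN:
            logger.warning(
                "cross_validate: training fold has %d samples; at least %d recommended",
                len(train_ids),
                RECOMMENDED_MIN_TRAIN,
            )
        X_tr = X.select(train_ids)
        Y_tr = Y.select(train_ids)
        X_te = X.select(fold)
        if method == "multiprobe-LM":
            mset = fit_multiprobe(X_tr, Y_tr, out_probes, k=k)
            res = predict_multiprobe(mset, X_te)
        else:
            mset = fit_probe_models(X_tr, Y_tr, method, epsilon=epsilon, cost=cost)
            res = predict_matrix(mset, X_te.select(probes=out_probes))
        pred.loc[fold, out_probes] = res.values.loc[fold, out_probes]
        n_oor += res.n_out_of_range
    Y_eval = Y.select(probes=out_probes) if target_probes is not None else Y
    report = _build_report(Y_eval, pred, method, n_oor, len(folds))
    result = PredictionResult(values=pred, n_out_of_range=n_oor, method=method)
    return result, report


def cross_tissue_correlation(
    X: BetaMatrix,
    Y: BetaMatrix,
    filters: Sequence[ExtremeProbeFilter] = DEFAULT_EXTREME_FILTERS,
) -> pd.DataFrame:
    """Per-sample R² between two tissues, raw and under extreme-probe filters.

    One row per filter level (``all_probes`` first): mean/min/max of the
    per-sample squared correlations, the number of probes removed, and the
    number used.
    """
    if X.sample_ids != Y.sample_ids or X.probe_ids != Y.probe_ids:
        raise ValidationError("X and Y must be aligned (same samples and probes, same order)")

    def _row(label: str, probes: list) -> dict:
        Xs = X.data[probes]
        Ys = Y.data[probes]
        r2s = np.array(
            [sample_r2(Xs.loc[s], Ys.loc[s]) for s in X.sample_ids], dtype=float
        )
        return {
            "filter": label,
            "mean_r2": float(np.nanmean(r2s)) if np.isfinite(r2s).any() else np.nan,
            "min_r2": float(np.nanmin(r2s)) if np.isfinite(r2s).any() else np.nan,
            "max_r2": float(np.nanmax(r2s)) if np.isfinite(r2s).any() else np.nan,
            "probes_removed": X.n_probes - len(probes),
            "n_probes_used": len(probes),
        }

    rows = [_row("all_probes", X.probe_ids)]
    for f in filters:
        kept = filter_extreme_probes([X, Y], f)
        rows.append(_row(f.label, kept))
    return pd.DataFrame(rows).set_index("filter")


def accuracy_by_variability(report: AccuracyReport, bin_width: float = 0.05) -> pd.DataFrame:
    """Stratify per-probe accuracy by target-tissue standard deviation.

    Returns, per SD bin: probe count, mean R², mean MAE, and the fraction of
    probes whose MAE lies below one target-tissue SD.
    """
    pp = report.per_probe
    sd = pp["sd_target"].to_numpy(dtype=float)
    finite_sd = sd[~np.isnan(sd)]
    if finite_sd.size == 0:
        raise ValidationError("report carries no per-probe SD values")
    max_sd = float(finite_sd.max())
    if max_sd == 0.0:
        logger.warning("accuracy_by_variability: all probes have zero target SD (degenerate stratum)")
    n_bins = max(1, int(np.ceil(max_sd / bin_width)) if max_sd > 0 else 1)
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    idx = np.clip(np.floor(sd / bin_width).astype(float), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        sub = pp.loc[sel]
        below = sub["mae"] < sub["sd_target"]
        rows.append(
            {
                "sd_low": edges[b],
                "sd_high": edges[b + 1],
                "n_probes": int(sel.sum()),
                "mean_r2": float(np.nanmean(sub["r2"])) if sub["r2"].notna().any() else np.nan,
                "mean_mae": float(np.nanmean(sub["mae"])) if sub["mae"].notna().any() else np.nan,
                "frac_mae_below_sd": float(below[sub["mae"].notna()].mean())
                if sub["mae"].notna().any()
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BinDensitySummary:
    """Within-bin densities of raw and calibrated values by true-target decile.

    ``table`` has one row per bin: the bin interval, the number of probes
    whose true target value falls in the bin, and for each supplied series
    the fraction of its values (at those probes) falling inside the bin.
    ``values`` maps each series name to the per-bin collections.
    """

    edges: np.ndarray
    table: pd.DataFrame
    values: dict


def density_by_bin(
    true_target_row,
    surrogate_row,
    lm_pred_row=None,
    svr_pred_row=None,
    n_bins: int = 10,
) -> BinDensitySummary:
    """Bin probes by the true target value into ``n_bins`` equal intervals of
    [0, 1] and measure how often each series falls inside the bin.

    Bins are left-closed right-open; the last bin also includes 1.0.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    t = np.asarray(true_target_row, dtype=float)
    series = {"raw_surrogate": np.asarray(surrogate_row, dtype=float)}
    if lm_pred_row is not None:
        series["lm_prediction"] = np.asarray(lm_pred_row, dtype=float)
    if svr_pred_row is not None:
        series["svr_prediction"] = np.asarray(svr_pred_row, dtype=float)
    for name, v in series.items():
        if v.shape != t.shape:
            raise ValidationError(f"{name} is not aligned with the true target vector")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    with np.errstate(invalid="ignore"):
        bin_idx = np.clip(np.floor(t * n_bins), 0, n_bins - 1)
    rows = []
    collections: dict = {name: [] for name in series}
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        sel = (~np.isnan(t)) & (bin_idx == b)
        row = {"bin_low": lo, "bin_high": hi, "n_true": int(sel.sum())}
        for name, v in series.items():
            vals = v[sel]
            vals = vals[~np.isnan(vals)]
            collections[name].append(vals)
            if b == n_bins - 1:
                inside = (vals >= lo) & (vals <= hi)
            else:
                inside = (vals >= lo) & (vals < hi)
            row[f"frac_{name}"] = float(inside.mean()) if vals.size else np.nan
        rows.append(row)
    return BinDensitySummary(edges=edges, table=pd.DataFrame(rows), values=collections)


def sample_size_experiment(
    X_train: BetaMatrix,
    Y_train: BetaMatrix,
    X_test: BetaMatrix,
    Y_test: BetaMatrix,
    sizes: Sequence[int] | None = None,
    replicates: int = 10,
    methods: Sequence[str] = ("LM", "SVR"),
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy of cross-study prediction as the training size varies.

    For each size a random training subset is drawn ``replicates`` times (the
    full-size entry runs once on all samples), both models are fitted and
    applied to the held-out study, and the per-sample mean absolute
    difference across probes plus the mean per-probe MAE are recorded. Each
    (seed, size, replicate) cell has its own RNG stream, so any cell is
    independently reproducible.
    """
    if sizes is None:
        sizes = [s for s in DEFAULT_SAMPLE_SIZES if s <= X_train.n_samples]
    n = X_train.n_samples
    for s in sizes:
        if s < 3:
            raise ValidationError(
                f"training size {s} is below the minimum of 3 paired samples per probe"
            )
        if s > n:
            raise ValidationError(f"training size {s} exceeds available samples ({n})")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if min(sizes) < RECOMMENDED_MIN_TRAIN:
        warnings.warn(
            f"training sizes below {RECOMMENDED_MIN_TRAIN} samples are examined; "
            "accuracy at those sizes is expected to be poor",
            stacklevel=2,
        )
    Xte = X_test
    rows = []
    for size in sizes:
        reps = 1 if size == n else replicates
        for rep in range(reps):
            rng = np.random.default_rng([seed, size, rep])
            idx = np.sort(rng.choice(n, size=size, replace=False))
            subset = [X_train.sample_ids[i] for i in idx]
            X_sub = X_train.select(subset)
            Y_sub = Y_train.select(subset)
            for method in methods:
                mset = fit_probe_models(X_sub, Y_sub, method)
                res = predict_matrix(mset, Xte)
                per_sample = [
                    sample_mae(Y_test.data.loc[s], res.values.loc[s])
                    for s in Y_test.sample_ids
                ]
                per_probe = [
                    probe_mae(Y_test.data[p], res.values[p]) for p in Y_test.probe_ids
                ]
                rows.append(
                    {
                        "size": size,
                        "replicate": rep,
                        "method": method,
                        "mean_abs_error": float(np.nanmean(per_sample)),
                        "mean_probe_mae": float(np.nanmean(per_probe)),
                    }
                )
    return pd.DataFrame(rows)
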