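"""Per-CpG cross-tissue calibration models.

For each probe j the target-tissue methylation y_j is modelled as a function
of the surrogate-tissue methylation x_j measured in the same individuals:

* **LM** -- ordinary least squares ``y_ij = a_j + b_j x_ij + e_ij``; a new
  sample's target methylation is predicted as ``a_j + b_j x_new``. Linear
  predictions can fall outside [0, 1] under extrapolation; they are reported
  unclamped (and counted) because that behaviour is a documented property of
  the model.
* **SVR** -- epsilon-insensitive support-vector regression with an RBF
  kernel, the e1071-equivalent defaults: epsilon 0.1, cost 1, kernel width
  gamma = 1 / #predictors, inputs and outputs standardized before fitting
  with the transform inverted at prediction. SVR predictions are confined to
  the range of the training targets -- the model's defining contrast with
  the LM -- enforced by clipping to the recorded training range.
* **multi-probe LM** -- a multivariate extension where the same-id surrogate
  probe plus the K-1 surrogate probes most correlated with the target probe
  (absolute Pearson correlation in training data, ties broken by probe id)
  enter a joint least-squares fit. With K = 1 it reduces exactly to the
  single-probe LM.

Fitting uses pairwise-complete observations per probe. Probes with fewer
than three usable pairs are flagged (``insufficient_data``) and predict
missing values rather than being silently dropped. Model sets serialize to a
versioned JSON container so that a model trained on one study can be applied
to another.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .core_io import BetaMatrix, ValidationError

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

__all__ = [
    "LinearProbeModel",
    "SvrProbeModel",
    "ProbeModelSet",
    "MultiProbeModel",
    "MultiProbePredictorSet",
    "PredictionResult",
    "fit_linear_probe",
    "predict_linear_probe",
    "fit_svr_probe",
    "fit_probe_models",
    "predict_matrix",
    "select_multiprobe_predictors",
    "fit_multiprobe",
    "predict_multiprobe",
    "select_target_probes_for_multiprobe",
    "save_model_set",
    "load_model_set",
    "model_set_to_dict",
    "model_set_from_dict",
]


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    ok = ~np.isnan(x) & ~np.isnan(y)
    return x[ok], y[ok]


@dataclass
class LinearProbeModel:
    """OLS calibration for one probe: intercept a_j, slope b_j."""

    probe_id: str
    intercept: float
    slope: float
    n_obs: int
    flag: str | None = None  # None | "constant_x" | "insufficient_data"

    def predict(self, x_new) -> np.ndarray:
        x = np.asarray(x_new, dtype=float)
        if self.flag == "insufficient_data":
            return np.full(x.shape, np.nan)
        return self.intercept + self.slope * x


def fit_linear_probe(x, y, probe_id: str = "") -> LinearProbeModel:
    """Least squares on pairwise-complete (x, y): slope = cov(x,y)/var(x).

    Constant x falls back to an intercept-only model predicting mean(y);
    fewer than three pairs yields an ``insufficient_data`` flag.
    """
    xp, yp = _paired(x, y)
    n = xp.size
    if n < 3:
        return LinearProbeModel(probe_id, np.nan, np.nan, n, "insufficient_data")
    mx = xp.mean()
    my = yp.mean()
    dx = xp - mx
    var_x = float(dx @ dx)
    if var_x <= 1e-24 * n:
        return LinearProbeModel(probe_id, float(my), 0.0, n, "constant_x")
    slope = float(dx @ (yp - my)) / var_x
    intercept = float(my - slope * mx)
    return LinearProbeModel(probe_id, intercept, float(slope), n, None)


def predict_linear_probe(m: LinearProbeModel, x_new):
    """Plug-in prediction a + b * x_new; values outside [0, 1] are returned
    unclamped."""
    return m.predict(x_new)


@dataclass
class SvrProbeModel:
    """RBF epsilon-SVR calibration for one probe.

    The fitted machine is stored explicitly (standardized support vector
    coordinates, dual coefficients, bias) so that prediction is a pure
    function of the recorded numbers and the model serializes to JSON.
    Predictions are confined to ``[y_min, y_max]``, the target range seen in
    training.
    """

    probe_id: str
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    bias: float
    gamma: float
    x_mean: float
    x_sd: float
    y_mean: float
    y_sd: float
    y_min: float
    y_max: float
    n_obs: int
    epsilon: float = 0.1
    cost: float = 1.0
    flag: str | None = None  # None | "constant_y" | "insufficient_data"

    @property
    def training_y_range(self) -> tuple[float, float]:
        return (self.y_min, self.y_max)

    def predict(self, x_new) -> np.ndarray:
        x = np.asarray(x_new, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        out = np.full(x.shape, np.nan)
        ok = ~np.isnan(x)
        if self.flag == "insufficient_data":
            return float(out[0]) if scalar else out
        if self.flag == "constant_y" or self.support_vectors.size == 0:
            out[ok] = self.y_mean
        else:
            z = (x[ok] - self.x_mean) / self.x_sd
            k = np.exp(-self.gamma * (z[:, None] - self.support_vectors[None, :]) ** 2)
            f = k @ self.dual_coef + self.bias
            out[ok] = np.clip(f * self.y_sd + self.y_mean, self.y_min, self.y_max)
        return float(out[0]) if scalar else out


def fit_svr_probe(
    x,
    y,
    probe_id: str = "",
    epsilon: float = 0.1,
    cost: float = 1.0,
    gamma: float | None = None,
) -> SvrProbeModel:
    """Fit epsilon-SVR of y on x with RBF kernel and e1071-equivalent defaults.

    x and y are standardized before fitting (sd with n-1 denominator, as in
    the reference implementation) and the output transform is inverted at
    prediction. A constant target yields a flagged constant model.
    """
    xp, yp = _paired(x, y)
    n = xp.size
    if n < 3:
        return SvrProbeModel(
            probe_id, np.empty(0), np.empty(0), 0.0, 1.0, 0.0, 1.0, np.nan, 1.0,
            np.nan, np.nan, n, epsilon, cost, "insufficient_data",
        )
    y_min, y_max = float(yp.min()), float(yp.max())
    y_mean = float(yp.mean())
    y_sd = float(yp.std(ddof=1))
    if y_sd <= 1e-12:
        return SvrProbeModel(
            probe_id, np.empty(0), np.empty(0), 0.0, 1.0, 0.0, 1.0, y_mean, 1.0,
            y_min, y_max, n, epsilon, cost, "constant_y",
        )
    x_mean = float(xp.mean())
    x_sd = float(xp.std(ddof=1))
    if x_sd <= 1e-12:
        x_sd = 1.0
    g = 1.0 if gamma is None else float(gamma)  # 1 / #predictors, one predictor
    zx = (xp - x_mean) / x_sd
    zy = (yp - y_mean) / y_sd
    svr = SVR(kernel="rbf", C=cost, epsilon=epsilon, gamma=g)
    svr.fit(zx.reshape(-1, 1), zy)
    return SvrProbeModel(
        probe_id=probe_id,
        support_vectors=svr.support_vectors_[:, 0].copy(),
        dual_coef=svr.dual_coef_[0].copy(),
        bias=float(svr.intercept_[0]),
        gamma=g,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        y_min=y_min,
        y_max=y_max,
        n_obs=n,
        epsilon=epsilon,
        cost=cost,
    )


@dataclass
class ProbeModelSet:
    """One fitted calibration model per probe."""

    method: str  # "LM" | "SVR"
    models: dict
    n_train: int

    @property
    def probe_ids(self) -> list:
        return list(self.models.keys())


@dataclass
class PredictionResult:
    """Predicted target-tissue methylation; LM values may exceed [0, 1]."""

    values: pd.DataFrame
    n_out_of_range: int
    method: str

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list:
        return list(self.values.columns)


def fit_probe_models(
    X: BetaMatrix,
    Y: BetaMatrix,
    method: str = "LM",
    epsilon: float = 0.1,
    cost: float = 1.0,
) -> ProbeModelSet:
    """Fit one calibration model per probe on aligned training matrices.

    Requires identical sample and probe ordering (use
    :func:`crossmeth.core_io.align_matrices` first). Each probe uses the
    samples where both tissues are non-missing.
    """
    if X.sample_ids != Y.sample_ids or X.probe_ids != Y.probe_ids:
        raise ValidationError("X and Y must be aligned (same samples and probes, same order)")
    models: dict = {}
    if method == "LM":
        A = X.values
        B = Y.values
        pair = ~np.isnan(A) & ~np.isnan(B)
        Ax = np.where(pair, A, 0.0)
        By = np.where(pair, B, 0.0)
        n = pair.sum(axis=0).astype(float)
        sx = Ax.sum(axis=0)
        sy = By.sum(axis=0)
        sxx = (Ax * Ax).sum(axis=0)
        sxy = (Ax * By).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            var_x = sxx - sx * sx / np.where(n > 0, n, 1.0)
            cov_xy = sxy - sx * sy / np.where(n > 0, n, 1.0)
        for j, pid in enumerate(X.probe_ids):
            nj = int(n[j])
            if nj < 3:
                models[pid] = LinearProbeModel(pid, np.nan, np.nan, nj, "insufficient_data")
            elif var_x[j] <= 1e-24 * nj:
                models[pid] = LinearProbeModel(pid, float(sy[j] / nj), 0.0, nj, "constant_x")
            else:
                slope = float(cov_xy[j] / var_x[j])
                intercept = float(sy[j] / nj - slope * sx[j] / nj)
                models[pid] = LinearProbeModel(pid, intercept, slope, nj, None)
    elif method == "SVR":
        for pid in X.probe_ids:
            models[pid] = fit_svr_probe(
                X.data[pid].to_numpy(), Y.data[pid].to_numpy(), pid, epsilon, cost
            )
    else:
        raise ValueError(f"unknown method {method!r} (expected 'LM' or 'SVR')")
    usable = sum(1 for m in models.values() if m.flag != "insufficient_data")
    if usable == 0:
        raise ValidationError("no probe has enough paired observations to fit a model")
    if usable < len(models):
        logger.info(
            "fit_probe_models(%s): %d of %d probes flagged insufficient_data",
            method,
            len(models) - usable,
            len(models),
        )
    return ProbeModelSet(method=method, models=models, n_train=X.n_samples)


def predict_matrix(models: ProbeModelSet, X_new: BetaMatrix) -> PredictionResult:
    """Apply a fitted model set to a new surrogate matrix, probe by probe.

    Missing surrogate cells yield missing predictions. LM predictions outside
    [0, 1] are preserved and counted.
    """
    unknown = [p for p in X_new.probe_ids if p not in models.models]
    if unknown:
        raise ValidationError(f"probes without a fitted model: {unknown[:5]}")
    out = np.empty((X_new.n_samples, X_new.n_probes))
    if models.method == "LM":
        intercepts = np.array([models.models[p].intercept for p in X_new.probe_ids])
        slopes = np.array([models.models[p].slope for p in X_new.probe_ids])
        out = intercepts[None, :] + slopes[None, :] * X_new.values
    else:
        for j, pid in enumerate(X_new.probe_ids):
            out[:, j] = models.models[pid].predict(X_new.data[pid].to_numpy())
    with np.errstate(invalid="ignore"):
        n_oor = int(((out < 0.0) | (out > 1.0)).sum())
    if n_oor:
        logger.info("predict_matrix(%s): %d predictions outside [0, 1]", models.method, n_oor)
    values = pd.DataFrame(out, index=X_new.sample_ids, columns=X_new.probe_ids)
    return PredictionResult(values=values, n_out_of_range=n_oor, method=models.method)


# -- multi-probe extension -------------------------------------------------


def _abs_corr_with(X: BetaMatrix, y: np.ndarray) -> pd.Series:
    """Pairwise-complete |Pearson r| between each surrogate probe and y."""
    A = X.values
    out = np.full(A.shape[1], np.nan)
    for j in range(A.shape[1]):
        xj = A[:, j]
        ok = ~np.isnan(xj) & ~np.isnan(y)
        if ok.sum() < 3:
            continue
        a = xj[ok]
        b = y[ok]
        sa = a.std()
        sb = b.std()
        if sa <= 0 or sb <= 0:
            continue
        out[j] = abs(np.corrcoef(a, b)[0, 1])
    return pd.Series(out, index=X.probe_ids)


def select_multiprobe_predictors(X: BetaMatrix, y_j: pd.Series, k: int) -> list:
    """Choose the same-id surrogate probe plus the k-1 most |r|-correlated
    surrogate probes; ties break lexicographically by probe id."""
    n = X.n_samples
    if k >= n - 1:
        raise ValidationError(f"K={k} predictors with n={n} samples is overparameterized")
    if k < 1:
        raise ValidationError("K must be >= 1")
    target_id = y_j.name
    if target_id not in X.data.columns:
        raise ValidationError(f"surrogate matrix lacks the same-id probe {target_id!r}")
    if k == 1:
        return [target_id]
    y = y_j.reindex(X.sample_ids).to_numpy(dtype=float)
    r = _abs_corr_with(X, y).drop(labels=[target_id])
    ranked = sorted(
        ((pid, val) for pid, val in r.items() if not np.isnan(val)),
        key=lambda t: (-t[1], t[0]),
    )
    return [target_id] + [pid for pid, _ in ranked[: k - 1]]


@dataclass
class MultiProbeModel:
    """Multivariate linear calibration of one target probe on K surrogate probes."""

    target_probe: str
    predictor_ids: list
    intercept: float
    coefs: np.ndarray
    n_obs: int
    flag: str | None = None

    def predict(self, X_new: BetaMatrix) -> np.ndarray:
        if self.flag == "insufficient_data":
            return np.full(X_new.n_samples, np.nan)
        Z = X_new.data[self.predictor_ids].to_numpy(dtype=float)
        return self.intercept + Z @ self.coefs


@dataclass
class MultiProbePredictorSet:
    """Fitted multi-probe models keyed by target probe id."""

    models: dict
    k: int
    n_train: int

    @property
    def probe_ids(self) -> list:
        return list(self.models.keys())


def fit_multiprobe(
    X: BetaMatrix,
    Y: BetaMatrix,
    target_probe_ids: Sequence,
    k: int = 5,
) -> MultiProbePredictorSet:
    """Multivariate least squares of each target probe on its K selected
    surrogate predictors.

    K = 1 delegates to the closed-form single-probe fit, so the multi-probe
    model nests the single-probe LM exactly. Collinear predictors are dropped
    (greedy, in selection order) with a warning before refitting.
    """
    if X.sample_ids != Y.sample_ids:
        raise ValidationError("X and Y must share samples in the same order")
    n = X.n_samples
    if k >= n - 1:
        raise ValidationError(f"K={k} predictors with n={n} samples is overparameterized")
    missing = [p for p in target_probe_ids if p not in Y.data.columns]
    if missing:
        raise ValidationError(f"target probes absent from Y: {missing[:5]}")
    models: dict = {}
    for pid in target_probe_ids:
        y_j = Y.data[pid]
        sel = select_multiprobe_predictors(X, y_j, k)
        if k == 1:
            lm = fit_linear_probe(X.data[pid].to_numpy(), y_j.to_numpy(), pid)
            models[pid] = MultiProbeModel(
                pid, [pid], lm.intercept, np.array([lm.slope]), lm.n_obs, lm.flag
            )
            continue
        Z = X.data[sel].to_numpy(dtype=float)
        y = y_j.to_numpy(dtype=float)
        ok = ~np.isnan(y) & ~np.isnan(Z).any(axis=1)
        Zo, yo = Z[ok], y[ok]
        if ok.sum() < len(sel) + 2:
            models[pid] = MultiProbeModel(
                pid, sel, np.nan, np.full(len(sel), np.nan), int(ok.sum()), "insufficient_data"
            )
            continue
        design = np.column_stack([np.ones(Zo.shape[0]), Zo])
        kept = _independent_columns(design)
        if len(kept) < design.shape[1]:
            dropped = [sel[i - 1] for i in range(1, design.shape[1]) if i not in kept]
            logger.warning(
                "fit_multiprobe(%s): dropped collinear predictors %s", pid, dropped
            )
            sel = [sel[i - 1] for i in kept if i > 0]
            design = design[:, kept]
        coef, *_ = np.linalg.lstsq(design, yo, rcond=None)
        models[pid] = MultiProbeModel(
            pid, sel, float(coef[0]), coef[1:].copy(), int(ok.sum()), None
        )
    return MultiProbePredictorSet(models=models, k=k, n_train=n)


def _independent_columns(design: np.ndarray, tol: float = 1e-10) -> list:
    """Greedy selection of linearly independent columns, in order."""
    kept: list = []
    basis = np.empty((design.shape[0], 0))
    for i in range(design.shape[1]):
        candidate = np.column_stack([basis, design[:, i]])
        if np.linalg.matrix_rank(candidate, tol=tol) > basis.shape[1]:
            kept.append(i)
            basis = candidate
    return kept


def predict_multiprobe(mset: MultiProbePredictorSet, X_new: BetaMatrix) -> PredictionResult:
    out = np.empty((X_new.n_samples, len(mset.models)))
    for j, (pid, model) in enumerate(mset.models.items()):
        missing = [p for p in model.predictor_ids if p not in X_new.data.columns]
        if missing:
            raise ValidationError(f"surrogate matrix lacks predictors {missing[:5]} for {pid!r}")
        out[:, j] = model.predict(X_new)
    with np.errstate(invalid="ignore"):
        n_oor = int(((out < 0.0) | (out > 1.0)).sum())
    values = pd.DataFrame(out, index=X_new.sample_ids, columns=list(mset.models.keys()))
    return PredictionResult(values=values, n_out_of_range=n_oor, method="multiprobe-LM")


def select_target_probes_for_multiprobe(
    Y: BetaMatrix,
    raw_r2: pd.Series,
    sd_range: tuple[float, float] = (0.1, 0.2),
    r2_max: float = 0.3,
    count: int = 1000,
    seed: int = 0,
) -> list:
    """Seeded uniform sample of target probes with moderate variability and
    poor raw cross-tissue R² (the regime where extra predictors can help)."""
    sd = pd.Series(np.nanstd(Y.values, axis=0, ddof=1), index=Y.probe_ids)
    raw_r2 = raw_r2.reindex(Y.probe_ids)
    lo, hi = sd_range
    eligible = [
        p
        for p in Y.probe_ids
        if lo <= sd[p] <= hi and not np.isnan(raw_r2[p]) and raw_r2[p] < r2_max
    ]
    if len(eligible) <= count:
        if len(eligible) < count:
            logger.warning(
                "select_target_probes_for_multiprobe: only %d eligible probes (requested %d)",
                len(eligible),
                count,
            )
        return eligible
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=count, replace=False)
    return [eligible[i] for i in sorted(chosen)]


# -- serialization ---------------------------------------------------------


def model_set_to_dict(ms) -> dict:
    """Serialize a ProbeModelSet or MultiProbePredictorSet to plain JSON types."""
    from . import __version__

    if isinstance(ms, MultiProbePredictorSet):
        probes = {
            pid: {
                "predictor_ids": m.predictor_ids,
                "intercept": _jsonf(m.intercept),
                "coefs": [_jsonf(c) for c in m.coefs],
                "n_obs": m.n_obs,
                "flag": m.flag,
            }
            for pid, m in ms.models.items()
        }
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "software": f"crossmeth {__version__}",
            "method": "multiprobe-LM",
            "k": ms.k,
            "n_train": ms.n_train,
            "probes": probes,
        }
    probes = {}
    for pid, m in ms.models.items():
        if ms.method == "LM":
            probes[pid] = {
                "intercept": _jsonf(m.intercept),
                "slope": _jsonf(m.slope),
                "n_obs": m.n_obs,
                "flag": m.flag,
            }
        else:
            probes[pid] = {
                "support_vectors": [_jsonf(v) for v in m.support_vectors],
                "dual_coef": [_jsonf(v) for v in m.dual_coef],
                "bias": _jsonf(m.bias),
                "gamma": _jsonf(m.gamma),
                "x_mean": _jsonf(m.x_mean),
                "x_sd": _jsonf(m.x_sd),
                "y_mean": _jsonf(m.y_mean),
                "y_sd": _jsonf(m.y_sd),
                "y_min": _jsonf(m.y_min),
                "y_max": _jsonf(m.y_max),
                "n_obs": m.n_obs,
                "epsilon": _jsonf(m.epsilon),
                "cost": _jsonf(m.cost),
                "flag": m.flag,
            }
    return {
        "format_version": MODEL_FORMAT_VERSION,
        "software": f"crossmeth {__version__}",
        "method": ms.method,
        "n_train": ms.n_train,
        "probes": probes,
    }


def _jsonf(v):
    v = float(v)
    return None if np.isnan(v) else v


def _unjsonf(v) -> float:
    return np.nan if v is None else float(v)


def model_set_from_dict(d: dict):
    if d.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValidationError(f"unsupported model format version {d.get('format_version')!r}")
    method = d["method"]
    if method == "multiprobe-LM":
        models = {
            pid: MultiProbeModel(
                pid,
                list(p["predictor_ids"]),
                _unjsonf(p["intercept"]),
                np.array([_unjsonf(c) for c in p["coefs"]]),
                int(p["n_obs"]),
                p.get("flag"),
            )
            for pid, p in d["probes"].items()
        }
        return MultiProbePredictorSet(models=models, k=int(d["k"]), n_train=int(d["n_train"]))
    models = {}
    for pid, p in d["probes"].items():
        if method == "LM":
            models[pid] = LinearProbeModel(
                pid, _unjsonf(p["intercept"]), _unjsonf(p["slope"]), int(p["n_obs"]), p.get("flag")
            )
        elif method == "SVR":
            models[pid] = SvrProbeModel(
                probe_id=pid,
                support_vectors=np.array([_unjsonf(v) for v in p["support_vectors"]]),
                dual_coef=np.array([_unjsonf(v) for v in p["dual_coef"]]),
                bias=_unjsonf(p["bias"]),
                gamma=_unjsonf(p["gamma"]),
                x_mean=_unjsonf(p["x_mean"]),
                x_sd=_unjsonf(p["x_sd"]),
                y_mean=_unjsonf(p["y_mean"]),
                y_sd=_unjsonf(p["y_sd"]),
                y_min=_unjsonf(p["y_min"]),
                y_max=_unjsonf(p["y_max"]),
                n_obs=int(p["n_obs"]),
                epsilon=_unjsonf(p.get("epsilon", 0.1)),
                cost=_unjsonf(p.get("cost", 1.0)),
                flag=p.get("flag"),
            )
        else:
            raise ValidationError(f"unknown model method {method!r}")
    return ProbeModelSet(method=method, models=models, n_train=int(d["n_train"]))


def save_model_set(ms, path) -> None:
    Path(path).write_text(json.dumps(model_set_to_dict(ms)))


def load_model_set(path):
    return model_set_from_dict(json.loads(Path(path).read_text()))
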