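"""Cross-model feature relevance: PLSR weights, RF importance, GPR ARD.

Three of the roster families expose a native relevance score:

* PLSR — the weight vectors of the fitted components; a predictor's
  aggregate score is its maximum absolute weight across components
  (relevant in *any* component counts).
* Random forest — normalized impurity importances.
* GPR — per-dimension (ARD) kernel length scales, read as a *weakness*
  index: the larger the fitted length scale, the weaker the predictor.

Scores are not comparable across methods, so each method's predictors
are classified by quartile: the top quartile (score >= Q3) is relevant
for PLSR and random forest, the bottom quartile (score <= Q1) for the
GPR weakness index.  The per-method relevant sets are then merged into
a consensus count (1, 2 or 3 methods).  For band predictors, runs of
relevant bands narrower than 10 nm are reported as a single variable
centered on the run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.pipeline import Pipeline
from sklearn.utils.validation import check_is_fitted

from .errors import HyperspadError

__all__ = [
    "plsr_weights",
    "rf_importance",
    "gpr_weakness",
    "fit_ard_gpr",
    "quartile_classify",
    "consensus",
    "ImportanceTable",
    "merge_band_runs",
]

MERGE_RANGE_NM = 10.0


def _unwrap(model):
    if isinstance(model, Pipeline):
        return model.named_steps["model"]
    return model


def plsr_weights(model, n_components: int | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-component weight vectors and the max-|weight| aggregate.

    Returns ``(weights, aggregate)`` where ``weights`` is
    ``(n_predictors, n_components)`` and ``aggregate[j] =
    max_k |weights[j, k]|``.
    """
    pls = _unwrap(model)
    if not isinstance(pls, PLSRegression):
        raise HyperspadError("plsr_weights needs a fitted PLSRegression")
    check_is_fitted(pls)
    w = np.asarray(pls.x_weights_)
    if n_components is not None:
        if n_components > w.shape[1]:
            raise HyperspadError(
                f"model has {w.shape[1]} components, {n_components} requested"
            )
        w = w[:, :n_components]
    return w, np.max(np.abs(w), axis=1)


def rf_importance(model) -> np.ndarray:
    """Normalized impurity importances (sum to 1)."""
    rf = _unwrap(model)
    if not isinstance(rf, RandomForestRegressor):
        raise HyperspadError("rf_importance needs a fitted RandomForestRegressor")
    check_is_fitted(rf)
    imp = np.asarray(rf.feature_importances_, dtype=float)
    total = imp.sum()
    return imp / total if total > 0 else imp


def fit_ard_gpr(x: np.ndarray, y: np.ndarray, seed: int = 0,
                max_iter: int = 15) -> GaussianProcessRegressor:
    """Fit a GPR with a per-dimension (ARD) squared-exponential kernel.

    Inputs should be standardized; a warning is emitted if they are not,
    since unstandardized scales make length scales incomparable.  The
    marginal-likelihood optimization is capped at ``max_iter`` L-BFGS
    iterations — ranking length scales does not need the optimum to
    machine precision, and the cap keeps high-dimensional ARD fits fast.
    """
    x = np.asarray(x, dtype=float)
    mu, sd = x.mean(axis=0), x.std(axis=0)
    if np.any(np.abs(mu) > 0.1) or np.any(np.abs(sd - 1.0) > 0.1):
        warnings.warn(
            "ARD GPR inputs do not look standardized; length scales will "
            "not be comparable across predictors", UserWarning, stacklevel=2)
    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * RBF(length_scale=np.full(x.shape[1], 3.0),
                    length_scale_bounds=(1e-2, 1e4))
              + WhiteKernel(1e-2, (1e-8, 1e1)))

    def optimizer(obj_func, initial_theta, bounds):
        from scipy.optimize import minimize

        res = minimize(obj_func, initial_theta, method="L-BFGS-B", jac=True,
                       bounds=bounds, options={"maxiter": max_iter})
        return res.x, res.fun

    gpr = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                   optimizer=optimizer,
                                   n_restarts_optimizer=0, random_state=seed)
    gpr.fit(x, y)
    return gpr


def gpr_weakness(model) -> np.ndarray:
    """Fitted ARD length scale per predictor (larger = weaker)."""
    gpr = _unwrap(model)
    if not isinstance(gpr, GaussianProcessRegressor):
        raise HyperspadError("gpr_weakness needs a fitted GaussianProcessRegressor")
    check_is_fitted(gpr)
    scales = None
    for param, value in gpr.kernel_.get_params().items():
        if param.endswith("length_scale"):
            value = np.atleast_1d(np.asarray(value, dtype=float))
            if value.size > 1:
                scales = value
    if scales is None:
        raise HyperspadError(
            "GPR kernel is isotropic; ARD (per-dimension) length scales are "
            "required for a weakness index"
        )
    return scales


def quartile_classify(scores: np.ndarray, mode: str = "top") -> np.ndarray:
    """Boolean relevance mask by the inclusive quartile rule.

    ``top``: score >= Q3 (linear-interpolation quantile); ``bottom``:
    score <= Q1.  Ties on the threshold are kept, so the relevant set
    holds between 25% and 100% of the predictors.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 4:
        raise HyperspadError("quartile classification needs >= 4 scores")
    if mode == "top":
        return scores >= np.quantile(scores, 0.75)
    if mode == "bottom":
        return scores <= np.quantile(scores, 0.25)
    raise ValueError(f"mode must be 'top' or 'bottom', got {mode!r}")


@dataclass
class ImportanceTable:
    """Per-predictor relevance across methods plus the consensus count."""

    table: pd.DataFrame      # predictor, per-method score + relevant flags,
    #                          consensus_count
    ranges: pd.DataFrame | None = None   # merged band ranges (band predictors)


def consensus(sets: dict, scores: dict | None = None,
              predictor_names: list | None = None,
              wavelengths: np.ndarray | None = None) -> ImportanceTable:
    """Merge per-method relevant sets into 1/2/3-method consensus counts.

    ``sets`` maps method name -> boolean relevance mask (all the same
    length).  Optional ``scores`` adds the raw per-method scores to the
    table.  If ``wavelengths`` is given (band predictors), contiguous
    relevant runs narrower than 10 nm are merged into single reported
    ranges per consensus level.
    """
    if not sets:
        raise HyperspadError("consensus needs at least one method set")
    masks = {m: np.asarray(v, dtype=bool) for m, v in sets.items()}
    n = len(next(iter(masks.values())))
    if any(v.size != n for v in masks.values()):
        raise HyperspadError("method masks have different lengths")
    names = (list(predictor_names) if predictor_names is not None
             else [f"x{i}" for i in range(n)])
    count = np.sum(list(masks.values()), axis=0).astype(int)
    data = {"predictor": names}
    for method, mask in masks.items():
        if scores and method in scores:
            data[f"{method}_score"] = np.asarray(scores[method], dtype=float)
        data[f"{method}_relevant"] = mask
    data["consensus_count"] = count
    table = pd.DataFrame(data)
    ranges = None
    if wavelengths is not None:
        ranges = merge_band_runs(np.asarray(wavelengths, dtype=float), count)
    return ImportanceTable(table=table, ranges=ranges)


def merge_band_runs(wavelengths: np.ndarray, count: np.ndarray,
                    merge_nm: float = MERGE_RANGE_NM) -> pd.DataFrame:
    """Report relevant bands as ranges; short runs count as one variable.

    Consecutive relevant bands (same consensus count) whose total span is
    below ``merge_nm`` collapse to a single variable centered on the run.
    """
    rows = []
    i, n = 0, len(wavelengths)
    while i < n:
        if count[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and count[j + 1] == count[i]:
            j += 1
        lo, hi = wavelengths[i], wavelengths[j]
        rows.append({
            "start_nm": float(lo),
            "end_nm": float(hi),
            "center_nm": float((lo + hi) / 2.0),
            "n_bands": j - i + 1,
            "consensus_count": int(count[i]),
            "single_variable": bool(hi - lo < merge_nm),
        })
        i = j + 1
    return pd.DataFrame(rows)
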