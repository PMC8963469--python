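"""The learning engine: predictor sets, splitting, roster, strategies, metrics.

The workflow assembles a predictor matrix (all 272 bands, the 145 bands
the index registry touches, or the 60 vegetation indices), splits each
campaign 80/20 into training/testing and validation subsets with matched
SPAD distributions, trains a roster of 17 regression configurations
under two strategies, and scores them with R2 (5-fold cross-validation)
plus RMSE/MAE on the held-out validation subset.

Strategies
----------
*Sequential*: one model fitted on all campaigns pooled and applied to
every campaign.  *Retraining*: one model per campaign prefix — model i
is fitted on campaigns 1..i with hyperparameters tuned once on prefix 1
and frozen — and campaign i is predicted by model i.  With a single
campaign the two strategies coincide exactly.

Model selection keeps configurations whose validation RMSE and MAE are
both within an error threshold (default 5 SPAD units, the combined
meter accuracy and environmental bias of the chlorophyll reading).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    Matern,
    RationalQuadratic,
    WhiteKernel,
)
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .errors import HyperspadError, UndefinedResultError
from .indices import IndexDefinition, compute_matrix, registry_wavelengths
from .spectral_io import SampleTable, SensorModel

__all__ = [
    "Dataset",
    "ModelConfig",
    "FittedModel",
    "MetricsRecord",
    "default_roster",
    "r2_score",
    "rmse",
    "mae",
    "split_dataset",
    "make_dataset",
    "cross_validate_r2",
    "evaluate",
    "fit_sequential",
    "fit_retraining",
    "predict_retraining",
    "select_models",
    "correlation_matrix",
    "compare_distributions",
    "five_number_summary",
]

PREDICTOR_SETS = ("all_bands", "selected_bands", "vis")
ERROR_THRESHOLD = 5.0  # SPAD units, for RMSE and MAE jointly


# ---------------------------------------------------------------------------
# Metrics (the printed formulas; kept as plain functions on purpose)
# ---------------------------------------------------------------------------

def r2_score(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination, 1 - SSE / SST with the mean baseline."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedResultError("R^2 undefined for constant y")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / sst


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    return float(np.sqrt(np.mean((y - np.asarray(y_hat, dtype=float)) ** 2)))


def mae(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    return float(np.mean(np.abs(y - np.asarray(y_hat, dtype=float))))


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Predictor matrix, SPAD response and campaign labels."""

    x: np.ndarray
    y: np.ndarray
    campaign: np.ndarray
    predictor_set: str
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.campaign = np.asarray(self.campaign)
        if self.x.shape[0] != self.y.size or self.y.size != self.campaign.size:
            raise HyperspadError("x, y and campaign lengths disagree")
        if self.predictor_set not in PREDICTOR_SETS:
            raise HyperspadError(
                f"predictor_set must be one of {PREDICTOR_SETS}"
            )

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.x.shape[1]

    @property
    def campaigns(self) -> list:
        return list(pd.unique(self.campaign))

    def for_campaigns(self, labels) -> "Dataset":
        sel = np.isin(self.campaign, list(labels))
        return Dataset(self.x[sel], self.y[sel], self.campaign[sel],
                       self.predictor_set, self.feature_names)


def make_dataset(table: SampleTable, predictor_set: str,
                 registry: list[IndexDefinition] | None = None,
                 sensor: SensorModel | None = None) -> Dataset:
    """Assemble the predictor matrix for one of the three predictor sets.

    The table must already be on the sensor grid (resampled spectra).
    ``selected_bands`` is exactly the column subset of ``all_bands`` at
    the registry's unique wavelengths; ``vis`` evaluates the registry.
    """
    sensor = sensor or SensorModel()
    spectra = table.spectra
    if predictor_set == "all_bands":
        x = spectra
        names = [f"{w:.1f}" for w in table.wavelengths]
    elif predictor_set == "selected_bands":
        if registry is None:
            raise HyperspadError("selected_bands needs the index registry")
        sel_wl = registry_wavelengths(registry, sensor)
        cols = [int(np.argmin(np.abs(table.wavelengths - w))) for w in sel_wl]
        x = spectra[:, cols]
        names = [f"{table.wavelengths[c]:.1f}" for c in cols]
    elif predictor_set == "vis":
        if registry is None:
            raise HyperspadError("vis needs the index registry")
        x = compute_matrix(registry, spectra, table.wavelengths)
        names = [d.name for d in registry]
    else:
        raise HyperspadError(f"unknown predictor set {predictor_set!r}")
    return Dataset(x=x, y=table.spad, campaign=table.campaign,
                   predictor_set=predictor_set, feature_names=names)


def split_dataset(table: SampleTable, train_frac: float = 0.8,
                  seed: int = 0) -> tuple[SampleTable, SampleTable]:
    """Distribution-matched 80/20 split per campaign.

    Within each campaign the samples are sorted by SPAD and dealt into
    ``n_val = round((1 - train_frac) * n)`` quantile blocks; one sample
    per block (seeded) goes to validation.  This keeps the subset
    distributions as similar as possible.  A 108-sample campaign splits
    86/22 (round-half-even on 21.6).
    """
    rng = np.random.default_rng(seed)
    campaign = table.campaign
    y = table.spad
    val_mask = np.zeros(len(y), dtype=bool)
    for label in table.campaigns:
        idx = np.nonzero(campaign == label)[0]
        n = idx.size
        if n < 5:
            raise HyperspadError(
                f"campaign {label!r} has {n} samples; >= 5 needed to split"
            )
        n_val = max(1, int(round((1.0 - train_frac) * n)))
        order = idx[np.argsort(y[idx], kind="stable")]
        blocks = np.array_split(order, n_val)
        for block in blocks:
            val_mask[rng.choice(block)] = True
    return table.subset(~val_mask), table.subset(val_mask)


# ---------------------------------------------------------------------------
# Model roster
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """One roster entry: family, variant tag and hyperparameters."""

    name: str
    family: str
    variant: str = ""
    hyperparams: dict = field(default_factory=dict)
    needs_scaling: bool = False
    probabilistic: bool = False
    tunable: bool = False

    def build(self, n_features: int, seed: int = 0):
        """Instantiate the scikit-learn estimator behind this config."""
        hp = dict(self.hyperparams)
        if self.family == "linear":
            est = LinearRegression()
        elif self.family == "plsr":
            est = PLSRegression(n_components=hp.get("n_components", 7),
                                scale=True)
        elif self.family == "tree":
            est = DecisionTreeRegressor(
                min_samples_leaf=hp["min_samples_leaf"], random_state=seed)
        elif self.family == "boosted_trees":
            est = GradientBoostingRegressor(
                n_estimators=hp.get("n_estimators", 60),
                max_depth=hp.get("max_depth", 4), random_state=seed)
        elif self.family == "random_forest":
            est = RandomForestRegressor(
                n_estimators=hp.get("n_estimators", 60),
                min_samples_leaf=hp.get("min_samples_leaf", 8),
                random_state=seed, n_jobs=1)
        elif self.family == "svr":
            if hp.get("gamma") in ("fine", "medium", "coarse"):
                hp.pop("gamma")  # resolved from n_features after build
            est = SVR(**hp)
        elif self.family == "gpr":
            kernel = self._gpr_kernel(hp.get("kernel", "rbf"))
            est = GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, alpha=1e-10,
                n_restarts_optimizer=0, random_state=seed)
        else:
            raise HyperspadError(f"unknown model family {self.family!r}")
        if self.needs_scaling:
            return Pipeline([("scale", StandardScaler()), ("model", est)])
        return est

    @staticmethod
    def _gpr_kernel(kind: str):
        amp = ConstantKernel(1.0, (1e-3, 1e3))
        noise = WhiteKernel(1e-2, (1e-8, 1e1))
        if kind == "exponential":
            core = Matern(length_scale=1.0, length_scale_bounds=(1e-2, 1e4),
                          nu=0.5)
        elif kind == "rbf":
            core = RBF(length_scale=1.0, length_scale_bounds=(1e-2, 1e4))
        elif kind == "matern52":
            core = Matern(length_scale=1.0, length_scale_bounds=(1e-2, 1e4),
                          nu=2.5)
        elif kind == "rational_quadratic":
            core = RationalQuadratic(length_scale=1.0, alpha=1.0,
                                     length_scale_bounds=(1e-2, 1e4))
        else:
            raise HyperspadError(f"unknown GPR kernel {kind!r}")
        return amp * core + noise


def default_roster() -> list[ModelConfig]:
    """The 17-model roster: linear, PLSR, 3 trees, 2 ensembles, 6 SVR, 4 GPR.

    Tree sizes and Gaussian SVR kernel scales follow the fine/medium/
    coarse convention (leaf sizes 4/12/36; kernel scale sqrt(p)/4,
    sqrt(p), 4*sqrt(p) via gamma).  Ensembles use 60 medium trees.
    """
    roster = [
        ModelConfig("Linear", "linear"),
        ModelConfig("PLSR", "plsr", tunable=True),
        ModelConfig("TreeFine", "tree", "fine",
                    {"min_samples_leaf": 4}),
        ModelConfig("TreeMedium", "tree", "medium",
                    {"min_samples_leaf": 12}),
        ModelConfig("TreeCoarse", "tree", "coarse",
                    {"min_samples_leaf": 36}),
        ModelConfig("BoostedTrees", "boosted_trees", "medium-60",
                    {"n_estimators": 60, "max_depth": 4}),
        ModelConfig("RandomForest", "random_forest", "bagged-60",
                    {"n_estimators": 60, "min_samples_leaf": 8}),
        ModelConfig("SVRLinear", "svr", "linear",
                    {"kernel": "linear", "C": 10.0, "epsilon": 0.5},
                    needs_scaling=True),
        ModelConfig("SVRQuadratic", "svr", "quadratic",
                    {"kernel": "poly", "degree": 2, "C": 10.0,
                     "epsilon": 0.5}, needs_scaling=True),
        ModelConfig("SVRCubic", "svr", "cubic",
                    {"kernel": "poly", "degree": 3, "C": 10.0,
                     "epsilon": 0.5}, needs_scaling=True),
        ModelConfig("SVRFineGaussian", "svr", "fine-gaussian",
                    {"kernel": "rbf", "C": 10.0, "epsilon": 0.5,
                     "gamma": "fine"}, needs_scaling=True),
        ModelConfig("SVRMediumGaussian", "svr", "medium-gaussian",
                    {"kernel": "rbf", "C": 10.0, "epsilon": 0.5,
                     "gamma": "medium"}, needs_scaling=True),
        ModelConfig("SVRCoarseGaussian", "svr", "coarse-gaussian",
                    {"kernel": "rbf", "C": 10.0, "epsilon": 0.5,
                     "gamma": "coarse"}, needs_scaling=True),
        ModelConfig("GPRExponential", "gpr", "exponential",
                    {"kernel": "exponential"}, needs_scaling=True,
                    probabilistic=True),
        ModelConfig("GPRSquaredExponential", "gpr", "squared-exponential",
                    {"kernel": "rbf"}, needs_scaling=True,
                    probabilistic=True),
        ModelConfig("GPRMatern52", "gpr", "matern-5/2",
                    {"kernel": "matern52"}, needs_scaling=True,
                    probabilistic=True),
        ModelConfig("GPRRationalQuadratic", "gpr", "rational-quadratic",
                    {"kernel": "rational_quadratic"}, needs_scaling=True,
                    probabilistic=True),
    ]
    assert len(roster) == 17
    return roster


def _resolve_gamma(cfg: ModelConfig, est, n_features: int):
    """Translate fine/medium/coarse kernel scales into SVR gamma."""
    hp = cfg.hyperparams
    if cfg.family != "svr" or hp.get("gamma") not in ("fine", "medium",
                                                      "coarse"):
        return est
    scale = {"fine": np.sqrt(n_features) / 4.0,
             "medium": np.sqrt(n_features),
             "coarse": 4.0 * np.sqrt(n_features)}[hp["gamma"]]
    gamma = 1.0 / (scale ** 2)
    if isinstance(est, Pipeline):
        est.named_steps["model"].set_params(gamma=gamma)
    else:
        est.set_params(gamma=gamma)
    return est


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A fitted roster entry plus the provenance mapping needs later."""

    config: ModelConfig
    estimator: object
    predictor_set: str
    seed: int
    tuned: dict = field(default_factory=dict)
    training_campaigns: list = field(default_factory=list)
    strategy: str = "sequential"

    @property
    def name(self) -> str:
        return self.config.name

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(x)).ravel()

    def predict_std(self, x: np.ndarray) -> np.ndarray:
        """Predictive standard deviation (probabilistic models only)."""
        if not self.config.probabilistic:
            raise HyperspadError(
                f"{self.name} does not expose predictive uncertainty"
            )
        est = self.estimator
        if isinstance(est, Pipeline):
            xt = est.named_steps["scale"].transform(x)
            gpr = est.named_steps["model"]
        else:
            xt, gpr = x, est
        _, std = gpr.predict(xt, return_std=True)
        return np.asarray(std).ravel()


def _build(cfg: ModelConfig, n_features: int, seed: int):
    est = cfg.build(n_features, seed=seed)
    return _resolve_gamma(cfg, est, n_features)


def _tune_plsr(train: Dataset, seed: int, max_components: int = 15,
               k: int = 5) -> int:
    """Pick the PLSR component count minimizing 5-fold CV RMSE."""
    upper = int(min(max_components, train.p,
                    train.n - np.ceil(train.n / k) - 1))
    upper = max(upper, 1)
    best_nc, best_err = 1, np.inf
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    for nc in range(1, upper + 1):
        errs = []
        for tr, te in folds.split(train.x):
            model = PLSRegression(n_components=nc, scale=True)
            model.fit(train.x[tr], train.y[tr])
            errs.append(rmse(train.y[te],
                             model.predict(train.x[te]).ravel()))
        err = float(np.mean(errs))
        if err < best_err - 1e-12:
            best_nc, best_err = nc, err
    return best_nc


def cross_validate_r2(cfg: ModelConfig, train: Dataset, k: int = 5,
                      seed: int = 0) -> float:
    """Pooled out-of-fold R2 under k-fold cross-validation."""
    if train.n < k:
        raise HyperspadError(f"n={train.n} < k={k} folds")
    if np.all(train.y == train.y[0]):
        raise UndefinedResultError("R^2 undefined for constant y")
    tuned = {}
    if cfg.tunable and cfg.family == "plsr":
        tuned["n_components"] = _tune_plsr(train, seed, k=k)
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.empty(train.n)
    for tr, te in folds.split(train.x):
        cfg_i = replace(cfg, hyperparams={**cfg.hyperparams, **tuned})
        est = _build(cfg_i, train.p, seed)
        est.fit(train.x[tr], train.y[tr])
        pooled[te] = np.asarray(est.predict(train.x[te])).ravel()
    return r2_score(train.y, pooled)


def fit_sequential(cfg: ModelConfig, train: Dataset,
                   seed: int = 0) -> FittedModel:
    """One model fitted on all campaigns pooled (hyperparameters CV-tuned)."""
    tuned = {}
    if cfg.tunable and cfg.family == "plsr":
        tuned["n_components"] = _tune_plsr(train, seed)
    cfg_t = replace(cfg, hyperparams={**cfg.hyperparams, **tuned})
    est = _build(cfg_t, train.p, seed)
    est.fit(train.x, train.y)
    return FittedModel(config=cfg, estimator=est,
                       predictor_set=train.predictor_set, seed=seed,
                       tuned=tuned, training_campaigns=train.campaigns,
                       strategy="sequential")


def fit_retraining(cfg: ModelConfig, train: Dataset,
                   seed: int = 0) -> list[FittedModel]:
    """Cumulative prefix models t1, t1+t2, ..., t1+...+tk.

    Hyperparameters are tuned on the first prefix only and frozen for
    every later refit, keeping the model architecture fixed while the
    training set grows.
    """
    labels = train.campaigns
    if not labels:
        raise HyperspadError("training data spans no campaigns")
    tuned = {}
    first = train.for_campaigns(labels[:1])
    if cfg.tunable and cfg.family == "plsr":
        tuned["n_components"] = _tune_plsr(first, seed)
    models = []
    for i in range(1, len(labels) + 1):
        prefix = train.for_campaigns(labels[:i])
        cfg_t = replace(cfg, hyperparams={**cfg.hyperparams, **tuned})
        est = _build(cfg_t, prefix.p, seed)
        est.fit(prefix.x, prefix.y)
        models.append(FittedModel(config=cfg, estimator=est,
                                  predictor_set=train.predictor_set,
                                  seed=seed, tuned=tuned,
                                  training_campaigns=labels[:i],
                                  strategy="retraining"))
    return models


def predict_retraining(models: list[FittedModel],
                       data: Dataset) -> np.ndarray:
    """Campaign i predicted by prefix-i model; campaigns must be known."""
    labels = [m.training_campaigns[-1] for m in models]
    y_hat = np.full(data.n, np.nan)
    for label in data.campaigns:
        if label not in labels:
            raise HyperspadError(
                f"campaign {label!r} missing from the retraining sequence"
            )
        model = models[labels.index(label)]
        sel = data.campaign == label
        y_hat[sel] = model.predict(data.x[sel])
    return y_hat


# ---------------------------------------------------------------------------
# Evaluation, selection, diagnostics
# ---------------------------------------------------------------------------

@dataclass
class MetricsRecord:
    """R2/RMSE/MAE for one model under one strategy and predictor set."""

    model: str
    predictor_set: str
    strategy: str
    r2: float
    rmse: float
    mae: float
    scope: str = "all"
    per_campaign: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.mae < 0 or self.rmse + 1e-12 < self.mae:
            raise HyperspadError("metrics must satisfy RMSE >= MAE >= 0")
        if self.r2 > 1.0 + 1e-12:
            raise HyperspadError("R^2 cannot exceed 1")


def evaluate(model: FittedModel | list[FittedModel], validation: Dataset,
             r2_value: float = np.nan) -> MetricsRecord:
    """Score predictions on the validation subset (plus per-campaign)."""
    if validation.n == 0:
        raise HyperspadError("validation dataset is empty")
    if isinstance(model, list):
        y_hat = predict_retraining(model, validation)
        name, pset, strategy = (model[0].name, model[0].predictor_set,
                                "retraining")
    else:
        y_hat = model.predict(validation.x)
        name, pset, strategy = model.name, model.predictor_set, model.strategy
    per_campaign = {}
    for label in validation.campaigns:
        sel = validation.campaign == label
        per_campaign[label] = {
            "rmse": rmse(validation.y[sel], y_hat[sel]),
            "mae": mae(validation.y[sel], y_hat[sel]),
            "n": int(sel.sum()),
        }
    return MetricsRecord(model=name, predictor_set=pset, strategy=strategy,
                         r2=float(r2_value),
                         rmse=rmse(validation.y, y_hat),
                         mae=mae(validation.y, y_hat),
                         per_campaign=per_campaign)


def select_models(records: list[MetricsRecord],
                  threshold: float = ERROR_THRESHOLD
                  ) -> tuple[list[MetricsRecord], list[MetricsRecord]]:
    """Keep records with RMSE <= threshold AND MAE <= threshold.

    Returns (passing, excluded).
    """
    passing = [r for r in records
               if r.rmse <= threshold and r.mae <= threshold]
    excluded = [r for r in records if r not in passing]
    return passing, excluded


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    constant_columns: list[str]


def correlation_matrix(dataset: Dataset) -> CorrelationResult:
    """Pearson r between SPAD and every predictor (and among predictors).

    Constant columns are reported by name; their correlations are NaN in
    the matrix rather than silently dropped.
    """
    if dataset.n < 3:
        raise HyperspadError("need >= 3 samples for Pearson correlation")
    names = dataset.feature_names or [f"x{i}" for i in range(dataset.p)]
    frame = pd.DataFrame(dataset.x, columns=names)
    frame.insert(0, "spad", dataset.y)
    constant = [c for c in frame.columns if frame[c].nunique() <= 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = frame.corr(method="pearson")
    # pandas leaves constant columns NaN already; keep unit diagonal elsewhere
    return CorrelationResult(r=r, constant_columns=constant)


def five_number_summary(values: np.ndarray) -> tuple:
    v = np.asarray(values, dtype=float)
    return (float(v.min()), float(np.quantile(v, 0.25)),
            float(np.median(v)), float(np.quantile(v, 0.75)),
            float(v.max()))


def compare_distributions(predictions: dict, observed: dict,
                          gap_bound: float = 5.0) -> pd.DataFrame:
    """Five-number summaries of retrieved vs observed SPAD per campaign.

    ``predictions`` and ``observed`` map campaign label -> 1-D array.
    Campaigns missing on either side appear with NaN summaries; the
    ``flagged`` column marks |median gap| > ``gap_bound``.
    """
    rows = []
    for label in sorted(set(predictions) | set(observed)):
        p = predictions.get(label)
        o = observed.get(label)
        row = {"campaign": label}
        for tag, arr in (("pred", p), ("obs", o)):
            if arr is None or len(arr) == 0:
                summary = (np.nan,) * 5
            else:
                summary = five_number_summary(arr)
            for k, v in zip(("min", "q1", "median", "q3", "max"), summary):
                row[f"{tag}_{k}"] = v
        row["median_gap"] = row["pred_median"] - row["obs_median"]
        row["flagged"] = (not np.isfinite(row["median_gap"])
                          or abs(row["median_gap"]) > gap_bound)
        rows.append(row)
    return pd.DataFrame(rows)
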