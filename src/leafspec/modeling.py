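"""ANOVA-kernel support-vector regression and the evaluation harness.

The kernel is ``K(x, y) = (sum_i exp(-gamma (x_i - y_i)^2))^d`` — a power
of a sum of per-coordinate Gaussian similarities.  Regression is
epsilon-SVR on the precomputed Gram matrix, evaluated by k-fold (default 4)
cross-validation with pooled out-of-fold predictions and the metric triple:

* R^2  — squared Pearson correlation of predicted vs observed values
         (the regression-line convention; the identity-line form is also
         reported);
* RMSE — root mean squared prediction error;
* RE   — 100 * RMSE / mean(observed), a scale-free percentage.

The harness ranks single features by cross-validated skill and compares
named feature sets on one shared fold assignment so results are paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVR

from .errors import ConfigurationError
from .features import FeatureTable
from .fluorescence import compute_fluorescence_params
from .indices import builtin_index_catalog, compute_all_indices
from .preprocess import DenoiseConfig
from .spectra import SampleRecord

logger = logging.getLogger(__name__)

#: Default named feature sets of the three-way comparison.
DEFAULT_FEATURE_SETS = {
    "vi4": ["TVI", "MTVI1", "MTVI2", "MSAVI"],
    "fluor2": ["F740_F460", "F685_F460"],
    "combined": ["TVI", "MTVI1", "MTVI2", "MSAVI", "F740_F460", "F685_F460"],
}


@dataclass(frozen=True)
class KernelSpec:
    """ANOVA kernel parameters: per-coordinate width gamma and power d."""

    gamma: float = 1.0
    d: int = 1

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ConfigurationError("gamma must be > 0")
        if self.d < 1:
            raise ConfigurationError("kernel power d must be >= 1")


@dataclass(frozen=True)
class SvrConfig:
    """Support-vector regression configuration.

    ``kernel.gamma`` of None means the per-experiment default 1/p where p
    is the number of active features.
    """

    kernel: KernelSpec | None = None  # None -> gamma = 1/p, d = 1
    C: float = 10.0
    epsilon: float = 0.1
    standardize: bool = True
    #: nested coarse grid search (C in {1,10,100}, gamma in {0.1,1,10}/p)
    #: inside the training folds only; off by default for reproducibility
    grid_search: bool = False

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ConfigurationError("C must be > 0")
        if self.epsilon < 0:
            raise ConfigurationError("epsilon must be >= 0")

    def resolve_kernel(self, n_features: int) -> KernelSpec:
        if self.kernel is not None:
            return self.kernel
        return KernelSpec(gamma=1.0 / n_features, d=1)


@dataclass
class EvalResult:
    """Pooled cross-validated predictions and metrics for one feature set."""

    feature_set_name: str
    feature_names: list[str]
    sample_ids: list[str]
    fold_assignments: np.ndarray
    predictions: np.ndarray
    observed: np.ndarray
    r2: float
    r2_identity: float
    rmse: float
    re: float
    n: int


def anova_kernel(x: np.ndarray, y: np.ndarray, spec: KernelSpec) -> float:
    """Scalar ANOVA kernel between two feature vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    s = np.sum(np.exp(-spec.gamma * (x - y) ** 2))
    return float(s ** spec.d)


def gram_matrix(X: np.ndarray, Y: np.ndarray | None = None,
                spec: KernelSpec = KernelSpec()) -> np.ndarray:
    """Pairwise ANOVA kernel matrix between rows of X and rows of Y."""
    X = np.atleast_2d(np.asarray(X, float))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("feature dimensionality mismatch")
    diff = X[:, None, :] - Y[None, :, :]
    return np.exp(-spec.gamma * diff ** 2).sum(axis=-1) ** spec.d


def fit_predict_svr(X_train: np.ndarray, y_train: np.ndarray,
                    X_test: np.ndarray, cfg: SvrConfig | None = None
                    ) -> np.ndarray:
    """Train epsilon-SVR with the ANOVA Gram matrix, predict test rows.

    Standardization statistics come from the training rows only.  An
    all-constant label vector short-circuits to constant predictions.
    """
    cfg = cfg or SvrConfig()
    X_train = np.atleast_2d(np.asarray(X_train, float))
    X_test = np.atleast_2d(np.asarray(X_test, float))
    y_train = np.asarray(y_train, float)
    if len(X_train) < 2:
        raise ValueError("need at least 2 training rows")
    if not (np.isfinite(X_train).all() and np.isfinite(X_test).all()
            and np.isfinite(y_train).all()):
        raise ValueError("non-finite values in model inputs; drop sentinel "
                         "rows before fitting")
    if np.ptp(y_train) == 0.0:
        logger.warning("degenerate fit: constant training labels")
        return np.full(len(X_test), y_train[0])

    if cfg.standardize:
        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0)
        sd[sd == 0] = 1.0
        X_train = (X_train - mu) / sd
        X_test = (X_test - mu) / sd

    spec = cfg.resolve_kernel(X_train.shape[1])
    C = cfg.C
    if cfg.grid_search:
        C, spec = _grid_search(X_train, y_train, cfg)
    model = SVR(kernel="precomputed", C=C, epsilon=cfg.epsilon)
    model.fit(gram_matrix(X_train, spec=spec), y_train)
    return model.predict(gram_matrix(X_test, X_train, spec=spec))


def _grid_search(X: np.ndarray, y: np.ndarray, cfg: SvrConfig,
                 inner_k: int = 3) -> tuple[float, KernelSpec]:
    """Coarse (C, gamma) selection by inner CV on the training rows only."""
    p = X.shape[1]
    base_gamma = cfg.resolve_kernel(p).gamma
    d = cfg.resolve_kernel(p).d
    inner = kfold_split(len(y), min(inner_k, len(y) // 2), seed=0)
    best = (float("inf"), cfg.C, KernelSpec(base_gamma, d))
    for C in (1.0, 10.0, 100.0):
        for scale in (0.1, 1.0, 10.0):
            spec = KernelSpec(base_gamma * scale, d)
            preds = np.empty(len(y))
            for f in np.unique(inner):
                test = inner == f
                model = SVR(kernel="precomputed", C=C, epsilon=cfg.epsilon)
                model.fit(gram_matrix(X[~test], spec=spec), y[~test])
                preds[test] = model.predict(
                    gram_matrix(X[test], X[~test], spec=spec))
            rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
            if rmse < best[0]:
                best = (rmse, C, spec)
    return best[1], best[2]


def kfold_split(n: int, k: int = 4, seed: int = 0) -> np.ndarray:
    """Random balanced fold assignment: array of fold indices in [0, k).

    Test-set sizes differ by at most one, larger folds first.
    """
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    folds = np.repeat(np.arange(k), sizes)
    return folds[rng.permutation(n)]


def metrics(predictions: np.ndarray, observed: np.ndarray
            ) -> tuple[float, float, float]:
    """(R^2, RMSE, RE) of predictions against observations.

    R^2 is the squared Pearson correlation (0 for zero-variance
    predictions, with a warning); RE requires a positive observed mean.
    """
    predictions = np.asarray(predictions, float)
    observed = np.asarray(observed, float)
    if predictions.shape != observed.shape or predictions.ndim != 1:
        raise ValueError("predictions and observations must be equal-length 1-D")
    if len(observed) < 2:
        raise ValueError("metrics need at least 2 samples")
    mean_obs = float(np.mean(observed))
    if mean_obs <= 0:
        raise ValueError("RE undefined: observed mean must be > 0")
    rmse = float(np.sqrt(np.mean((predictions - observed) ** 2)))
    re = 100.0 * rmse / mean_obs
    if np.std(predictions) == 0.0 or np.std(observed) == 0.0:
        logger.warning("zero-variance predictions or observations; R^2 set to 0")
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(predictions, observed)[0, 1] ** 2)
    return r2, rmse, re


def _r2_identity(predictions: np.ndarray, observed: np.ndarray) -> float:
    ss_tot = np.sum((observed - observed.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    return float(1.0 - np.sum((predictions - observed) ** 2) / ss_tot)


def cross_validate(X: np.ndarray, y: np.ndarray, cfg: SvrConfig | None = None,
                   k: int = 4, seed: int = 0,
                   folds: np.ndarray | None = None):
    """Pooled out-of-fold predictions for one feature matrix.

    Returns ``(predictions, fold_assignments)``; every sample is predicted
    exactly once by the model trained on the other folds.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    folds = kfold_split(len(y), k, seed) if folds is None else np.asarray(folds)
    preds = np.empty(len(y))
    for f in np.unique(folds):
        test = folds == f
        preds[test] = fit_predict_svr(X[~test], y[~test], X[test], cfg)
    return preds, folds


def _labeled(samples: list[SampleRecord], table: FeatureTable):
    ids = [r.sample_id for r in samples if r.has_label]
    y = np.array([r.lnc for r in samples if r.has_label], float)
    keep = [table.sample_ids.index(i) for i in ids]
    return FeatureTable(ids, list(table.feature_names),
                        table.values[keep]), y


def rank_single_features(samples: list[SampleRecord], table: FeatureTable,
                         cfg: SvrConfig | None = None, k: int = 4,
                         seed: int = 0) -> list[tuple[str, float]]:
    """Per-feature cross-validated skill ranking.

    Each feature column is used alone as the model input; samples with a
    sentinel in that column are dropped for that feature.  Returns
    (feature, pooled R^2) pairs sorted by descending R^2, ties broken by
    name.
    """
    sub, y = _labeled(samples, table)
    results: list[tuple[str, float]] = []
    for name in sub.feature_names:
        col = sub.column(name)
        ok = np.isfinite(col)
        if ok.sum() < 2 * k:
            logger.warning("feature %s: too few defined values; excluded", name)
            continue
        preds, _ = cross_validate(col[ok, None], y[ok], cfg, k, seed)
        r2, _, _ = metrics(preds, y[ok])
        results.append((name, r2))
    return sorted(results, key=lambda t: (-t[1], t[0]))


def assemble_feature_table(samples: list[SampleRecord],
                           denoise: DenoiseConfig | None = None,
                           far_red_center: float = 740.0,
                           msr_mode: str = "canonical",
                           rep_mode: str = "canonical") -> FeatureTable:
    """Full VI + fluorescence feature table for the given samples."""
    vi = compute_all_indices(
        samples, builtin_index_catalog(msr_mode, rep_mode), denoise)
    fl = compute_fluorescence_params(
        samples, far_red_center=far_red_center, denoise=denoise)
    return vi.hstack(fl)


def run_experiment(samples: list[SampleRecord],
                   feature_sets: dict[str, list[str]] | None = None,
                   cfg: SvrConfig | None = None, k: int = 4, seed: int = 0,
                   table: FeatureTable | None = None) -> list[EvalResult]:
    """Paired comparison of named feature sets under shared CV folds.

    Rows carrying a sentinel in a set's active features are dropped for
    that set only (with a logged count); the one seeded fold assignment is
    made on all labeled samples and restricted per set, so overlapping
    samples are always tested in the same fold.
    """
    feature_sets = feature_sets or DEFAULT_FEATURE_SETS
    if table is None:
        table = assemble_feature_table(samples)
    for name, feats in feature_sets.items():
        unknown = set(feats) - set(table.feature_names)
        if unknown:
            raise ConfigurationError(
                f"feature set {name!r} references unknown features "
                f"{sorted(unknown)}")
    sub, y = _labeled(samples, table)
    folds = kfold_split(len(y), k, seed)

    results: list[EvalResult] = []
    for set_name, feats in feature_sets.items():
        X = sub.select(feats).values
        ok = np.isfinite(X).all(axis=1)
        if (~ok).any():
            logger.warning("feature set %s: dropped %d sample(s) with "
                           "sentinel values", set_name, int((~ok).sum()))
        preds, used_folds = cross_validate(X[ok], y[ok], cfg, k, seed,
                                           folds=folds[ok])
        r2, rmse, re = metrics(preds, y[ok])
        results.append(EvalResult(
            feature_set_name=set_name,
            feature_names=list(feats),
            sample_ids=[i for i, keep in zip(sub.sample_ids, ok) if keep],
            fold_assignments=used_folds,
            predictions=preds,
            observed=y[ok],
            r2=r2,
            r2_identity=_r2_identity(preds, y[ok]),
            rmse=rmse,
            re=re,
            n=int(ok.sum()),
        ))
    return results
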