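"""Random-forest land-use regression of PM2.5 on road-traffic proxies.

Single-proxy and combined models are evaluated by k-fold cross-validation
(default 3 folds) with metrics computed on the pooled out-of-fold
predictions: R2, RMSE, MAE and mean bias error (MBE = mean(predicted -
observed)). Forest defaults follow the study configuration: 50 trees,
mtry = floor(sqrt(#predictors)) candidate features per split, bootstrap
sampling, unlimited depth. Feature importance (mean impurity decrease,
averaged over trees and folds, normalised to sum to 1) is reported for
combined models only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

FEATURE_COLUMNS = {"WRND": "wrnd_kmkm2", "EM": "em_km", "EH": "eh_km"}
FLAG_CONSTANT_TARGET = "constant-target"


@dataclass(frozen=True)
class ModelSpec:
    features: tuple[str, ...]  # subset of {"WRND", "EM", "EH"}
    stratum: str = "global"
    ntree: int = 50
    n_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("at least one feature is required")
        unknown = set(self.features) - set(FEATURE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    @property
    def mtry(self) -> int:
        return max(1, int(np.floor(np.sqrt(len(self.features)))))

    @property
    def name(self) -> str:
        return "Combined" if len(self.features) > 1 else self.features[0]


@dataclass
class ModelResult:
    spec: ModelSpec
    r2: float
    rmse: float
    mae: float
    mbe: float
    n: int
    per_fold_metrics: list[dict] = field(default_factory=list)
    oof_predictions: np.ndarray | None = None
    targets: np.ndarray | None = None
    importances: dict[str, float] | None = None  # combined models only
    flags: set[str] = field(default_factory=set)


@dataclass
class BiasProfile:
    bin_edges: np.ndarray  # ug/m3
    mean_bias: np.ndarray
    median_bias: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    n_per_bin: np.ndarray
    sparse_bins: np.ndarray  # True where n < 3


def _metrics(y: np.ndarray, yhat: np.ndarray) -> dict:
    resid = yhat - y
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return {
        "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
        "rmse": float(np.sqrt((resid**2).mean())),
        "mae": float(np.abs(resid).mean()),
        "mbe": float(resid.mean()),
        "n": int(y.size),
    }


def fit_rf_cv(data: pd.DataFrame, spec: ModelSpec, target: str = "pm25") -> ModelResult:
    """Cross-validated random forest; metrics on pooled out-of-fold
    predictions. Deterministic given (data, spec)."""
    cols = [FEATURE_COLUMNS[f] for f in spec.features]
    missing = [c for c in cols + [target] if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks columns {missing}")
    X = np.asarray(data[cols], dtype=float)
    y = np.asarray(data[target], dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("missing feature/target values; apply complete-case filtering upstream")
    n = y.size
    if n < spec.n_folds:
        raise ValueError(f"need at least n_folds={spec.n_folds} observations (got {n})")

    flags: set[str] = set()
    if np.all(y == y[0]):
        flags.add(FLAG_CONSTANT_TARGET)

    kf = KFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed % (2**32))
    oof = np.full(n, np.nan)
    per_fold = []
    fold_importances = []
    for k, (tr, te) in enumerate(kf.split(X)):
        rf = RandomForestRegressor(
            n_estimators=spec.ntree,
            max_features=spec.mtry,
            bootstrap=True,
            random_state=(spec.seed + 1000 * k) % (2**32),
        )
        rf.fit(X[tr], y[tr])
        oof[te] = rf.predict(X[te])
        m = _metrics(y[te], oof[te])
        m["fold"] = k
        per_fold.append(m)
        fold_importances.append(rf.feature_importances_)

    pooled = _metrics(y, oof)
    importances = None
    if len(spec.features) >= 2:
        imp = np.mean(fold_importances, axis=0)
        total = imp.sum()
        imp = imp / total if total > 0 else np.full_like(imp, 1.0 / imp.size)
        importances = dict(zip(spec.features, (float(v) for v in imp)))
    return ModelResult(
        spec=spec,
        r2=pooled["r2"],
        rmse=pooled["rmse"],
        mae=pooled["mae"],
        mbe=pooled["mbe"],
        n=n,
        per_fold_metrics=per_fold,
        oof_predictions=oof,
        targets=y,
        importances=importances,
        flags=flags,
    )


def feature_importance(result: ModelResult) -> dict[str, float]:
    """Normalised impurity-decrease importances of a combined model."""
    if result.importances is None:
        raise ValueError("feature importance is defined for combined (>= 2 feature) models only")
    return dict(result.importances)


MODEL_SETS: tuple[tuple[str, ...], ...] = (("WRND",), ("EM",), ("EH",), ("WRND", "EM", "EH"))


def run_model_suite(
    data: pd.DataFrame,
    strata: Sequence[str] | None = None,
    ntree: int = 50,
    n_folds: int = 3,
    seed: int = 0,
    target: str = "pm25",
) -> list[ModelResult]:
    """Four models (WRND, EM, EH, Combined) per stratum plus pooled
    "global". ``strata`` is a per-row label sequence; omit for global only."""
    results = []
    frames: list[tuple[str, pd.DataFrame]] = []
    if strata is not None:
        lab = pd.Series(list(strata), index=data.index)
        for s in sorted(set(lab)):
            frames.append((s, data[lab == s]))
    frames.append(("global", data))
    for stratum, frame in frames:
        for feats in MODEL_SETS:
            spec = ModelSpec(features=feats, stratum=stratum, ntree=ntree,
                             n_folds=n_folds, seed=seed)
            results.append(fit_rf_cv(frame, spec, target=target))
    return results


def metrics_table(results: Sequence[ModelResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.spec.stratum, r.spec.name, r.n, r.r2, r.rmse, r.mae, r.mbe) for r in results],
        columns=["stratum", "model", "n", "r2", "rmse", "mae", "mbe"],
    )


def binned_bias(
    oof_predictions: np.ndarray,
    targets: np.ndarray,
    bin_width: float = 20.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> BiasProfile:
    """Bias profile across observed-concentration bins.

    Observations are binned by observed PM2.5 in ``bin_width`` ug/m3 bins
    from 0; per-bin mean and median of (predicted - observed) are
    reported with a seeded nonparametric bootstrap 95% CI of the mean.
    Bins with fewer than 3 observations are flagged sparse.
    """
    yhat = np.asarray(oof_predictions, dtype=float)
    y = np.asarray(targets, dtype=float)
    if y.size == 0 or yhat.shape != y.shape:
        raise ValueError("predictions and targets must be non-empty and aligned")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    bias = yhat - y
    top = np.ceil(max(y.max(), 0) / bin_width) * bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([0.0, bin_width])
    idx = np.clip(np.digitize(y, edges) - 1, 0, edges.size - 2)
    nbins = edges.size - 1
    mean_b = np.full(nbins, np.nan)
    med_b = np.full(nbins, np.nan)
    lo = np.full(nbins, np.nan)
    hi = np.full(nbins, np.nan)
    counts = np.zeros(nbins, dtype=int)
    rng = np.random.default_rng(seed)
    for b in range(nbins):
        sel = bias[idx == b]
        counts[b] = sel.size
        if sel.size == 0:
            continue
        mean_b[b] = sel.mean()
        med_b[b] = float(np.median(sel))
        boot = rng.choice(sel, size=(n_boot, sel.size), replace=True).mean(axis=1)
        lo[b] = float(np.quantile(boot, 0.025))
        hi[b] = float(np.quantile(boot, 0.975))
    return BiasProfile(
        bin_edges=edges,
        mean_bias=mean_b,
        median_bias=med_b,
        ci95_low=lo,
        ci95_high=hi,
        n_per_bin=counts,
        sparse_bins=counts < 3,
    )


def bias_profile_table(profile: BiasProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_low": profile.bin_edges[:-1],
            "bin_high": profile.bin_edges[1:],
            "n": profile.n_per_bin,
            "mean_bias": profile.mean_bias,
            "median_bias": profile.median_bias,
            "ci95_low": profile.ci95_low,
            "ci95_high": profile.ci95_high,
            "sparse": profile.sparse_bins,
        }
    )
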