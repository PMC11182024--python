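"""Composite soil quality index and its microbial drivers.

The quality index is the per-sample mean of z-scored values (sample sd,
n - 1) of 13 soil variables: the enzymes APE, BG, XYL, LAP, PPO, UE, the
nutrients AK, AP, NH4, NO3, respiration, TN and TC. PPO enters as-is (no
sign inversion). Being an average of z-scores, the index is dimensionless,
has mean ~0 across samples and is invariant to affine rescaling of any
input variable.

Feature importance for the index is estimated with a bagged regression
forest whose out-of-bag (OOB) bookkeeping is explicit, so importance can be
reported the way R's randomForest prints it: %IncMSE, the percent increase
in OOB mean squared error after permuting one feature. Significance comes
from refitting on permuted targets and comparing each feature's observed
%IncMSE with its null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from .community import PermTestResult
from .synthetic import QUALITY_VARIABLES

__all__ = [
    "QUALITY_VARIABLES",
    "QualityIndex",
    "ImportanceResult",
    "quality_index",
    "group_compare",
    "feature_matrix",
    "importance",
]


@dataclass
class QualityIndex:
    index: pd.Series  # sample_id -> dimensionless quality score
    variables: tuple  # variables actually averaged (constants dropped)


@dataclass
class ImportanceResult:
    table: pd.DataFrame  # feature -> inc_mse_percent, p_value, significant
    variance_explained: float  # OOB R^2, <= 1
    seed: object = None
    n_trees: int = 0
    n_null: int = 0


def quality_index(soil: pd.DataFrame, variables=None) -> QualityIndex:
    """Average of z-scored soil variables per sample (the 13 defaults unless overridden)."""
    variables = tuple(QUALITY_VARIABLES if variables is None else variables)
    missing = [v for v in variables if v not in soil.columns]
    if missing:
        raise ValueError(f"missing soil variable(s): {missing}")
    if soil[list(variables)].isna().any().any():
        raise ValueError("soil variables contain missing values")
    used = []
    zs = []
    for var in variables:
        col = soil[var].astype(float)
        sd = col.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            import warnings

            warnings.warn(f"variable {var!r} is constant; dropped from the index", stacklevel=2)
            continue
        used.append(var)
        zs.append((col - col.mean()) / sd)
    if not used:
        raise ValueError("no non-constant variables left for the index")
    index = pd.concat(zs, axis=1).mean(axis=1).rename("quality_index")
    return QualityIndex(index=index, variables=tuple(used))


def group_compare(
    values: pd.Series,
    grouping: pd.Series,
    method: str = "t",
    n_perm: int = 999,
    seed=None,
) -> PermTestResult:
    """Two-sided two-group comparison of per-sample values.

    ``method="t"`` is a Welch t-test; ``method="permutation"`` permutes group
    labels and compares mean differences (the fallback for non-normal data).
    """
    grouping = grouping.reindex(values.index)
    if grouping.isna().any():
        raise ValueError("grouping missing for some samples")
    levels = grouping.unique()
    if levels.size != 2:
        raise ValueError("group_compare requires exactly two groups")
    a = values[grouping == levels[0]].to_numpy(dtype=float)
    b = values[grouping == levels[1]].to_numpy(dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 samples per group")
    if method == "t":
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if np.isclose(a.mean(), b.mean()):
                return PermTestResult(0.0, 1.0, 0, seed, "welch-t", degenerate=True)
            raise ValueError("zero-variance groups with different means")
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        return PermTestResult(float(stat), float(p), 0, seed, "welch-t")
    if method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            hits += abs(perm[: a.size].mean() - perm[a.size :].mean()) >= obs - 1e-12
        return PermTestResult(
            float(a.mean() - b.mean()), (1 + hits) / (1 + n_perm), n_perm, seed, "permutation"
        )
    raise ValueError(f"unknown method {method!r}")


def feature_matrix(
    metadata: pd.DataFrame,
    richness: dict,
    module_z: pd.DataFrame,
    treatment_metrics: pd.DataFrame | None = None,
    treatment_col: str = "residue",
) -> pd.DataFrame:
    """Assemble the samples x features predictor table for the forest.

    ``richness`` maps a group name (e.g. ``"bacterial"``) to a per-sample
    richness Series; ``module_z`` holds per-sample module abundance z-scores;
    ``treatment_metrics`` (optional) is indexed by treatment level with
    network-level columns (P/N ratio, robustness, connectedness...) that are
    broadcast to every member sample. Column order is deterministic:
    richness features (sorted by group name), module columns (as given),
    then treatment metrics (as given).
    """
    pieces = []
    for name in sorted(richness):
        series = richness[name].reindex(metadata.index)
        if series.isna().any():
            raise ValueError(f"richness[{name!r}] missing for some samples")
        pieces.append(series.rename(f"{name}_richness").astype(float))
    module_z = module_z.reindex(metadata.index)
    if module_z.isna().any().any():
        raise ValueError("module abundances missing for some samples")
    pieces.append(module_z)
    if treatment_metrics is not None:
        levels = metadata[treatment_col]
        missing = set(levels.unique()) - set(treatment_metrics.index)
        if missing:
            raise ValueError(f"treatment metrics missing for levels: {sorted(missing)}")
        broadcast = treatment_metrics.loc[levels].set_index(metadata.index)
        pieces.append(broadcast.astype(float))
    features = pd.concat(pieces, axis=1)
    if features.isna().any().any():
        raise ValueError("assembled feature matrix contains missing values")
    return features


def _fit_forest(x, y, n_trees, max_features, rng):
    """Bagged regression trees with recorded OOB indices per tree."""
    n = y.size
    trees = []
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeRegressor(
            max_features=max_features, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(x[boot], y[boot])
        trees.append((tree, oob))
    return trees


def _oob_mse(trees, x, y, permute_feature=None, rng=None):
    """OOB-aggregated MSE, optionally with one feature column permuted."""
    n = y.size
    pred_sum = np.zeros(n)
    pred_count = np.zeros(n)
    for tree, oob in trees:
        if oob.size == 0:
            continue
        x_oob = x[oob]
        if permute_feature is not None:
            x_oob = x_oob.copy()
            x_oob[:, permute_feature] = x_oob[rng.permutation(oob.size), permute_feature]
        pred_sum[oob] += tree.predict(x_oob)
        pred_count[oob] += 1
    covered = pred_count > 0
    residual = y[covered] - pred_sum[covered] / pred_count[covered]
    return float(np.mean(residual**2))


def _incmse(trees, x, y, rng):
    base = _oob_mse(trees, x, y)
    scale = base if base > 0 else np.var(y)
    out = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        out[j] = 100.0 * (_oob_mse(trees, x, y, permute_feature=j, rng=rng) - base) / scale
    return out, base


def importance(
    features: pd.DataFrame,
    target: pd.Series,
    n_trees: int = 1000,
    seed=None,
    n_null: int = 50,
    max_features: float = 1.0 / 3.0,
) -> ImportanceResult:
    """Random-forest %IncMSE importance of each feature for the quality index.

    Fits ``n_trees`` bagged regression trees (``max_features`` candidate
    fraction per split, the regression-forest convention), reports each
    feature's percent increase in OOB MSE under feature permutation, OOB
    variance explained, and a per-feature significance flag obtained by
    refitting on ``n_null`` permuted targets (p = (1 + b)/(1 + n_null),
    significant at 0.05). Deterministic given (data, seed).
    """
    features = features.astype(float)
    if features.shape[0] < 20:
        raise ValueError("need at least 20 samples")
    if features.isna().any().any() or target.reindex(features.index).isna().any():
        raise ValueError("missing values in features or target")
    y = target.reindex(features.index).to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("target is constant")
    x = features.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    trees = _fit_forest(x, y, n_trees, max_features, rng)
    observed, base_mse = _incmse(trees, x, y, rng)
    variance_explained = 1.0 - base_mse / np.var(y)

    p_values = np.full(observed.size, np.nan)
    if n_null > 0:
        null = np.empty((n_null, observed.size))
        for k in range(n_null):
            y_perm = rng.permutation(y)
            null_trees = _fit_forest(x, y_perm, n_trees, max_features, rng)
            null[k], _ = _incmse(null_trees, x, y_perm, rng)
        p_values = (1 + (null >= observed[None, :] - 1e-12).sum(axis=0)) / (1 + n_null)
    table = pd.DataFrame(
        {
            "inc_mse_percent": observed,
            "p_value": p_values,
            "significant": p_values <= 0.05,
        },
        index=features.columns,
    ).sort_values("inc_mse_percent", ascending=False)
    return ImportanceResult(
        table=table,
        variance_explained=float(variance_explained),
        seed=seed,
        n_trees=n_trees,
        n_null=n_null,
    )
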