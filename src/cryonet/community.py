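"""Diversity, ordination and permutation tests on community matrices.

Distance matrices are square symmetric ``DataFrame`` objects with matching id
index/columns. Permutation p-values use the (1 + b) / (1 + m) estimator, so a
p-value can never be zero and its floor is 1/(n_permutations + 1). For tiny
sample sets both PERMANOVA and the Mantel test accept
``n_perm="exhaustive"``, which enumerates every ordering; the Monte-Carlo
estimator is consistent with the exhaustive count because the identity
permutation plays the role of the "+1".
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PermTestResult",
    "OrdinationResult",
    "richness",
    "bray_curtis",
    "read_distance_matrix",
    "write_distance_matrix",
    "pcoa",
    "permanova",
    "permanova_factorial",
    "mantel",
]

_EXHAUSTIVE_LIMIT = 8  # 8! = 40320 orderings


@dataclass(frozen=True)
class PermTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: object = None
    method: str = ""
    degenerate: bool = False


@dataclass(frozen=True)
class OrdinationResult:
    """Principal coordinates: samples x axes scores scaled by sqrt(eigenvalue)."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def richness(table: pd.DataFrame) -> pd.Series:
    """Observed richness: number of taxa with count > 0 per sample."""
    return (table > 0).sum(axis=1).rename("richness")


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, d = sum|x - y| / sum(x + y)."""
    totals = table.sum(axis=1)
    if (totals == 0).any():
        raise ValueError(f"zero-total sample(s): {table.index[totals == 0].tolist()}")
    d = squareform(pdist(table.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


def _check_distance(dist: pd.DataFrame) -> np.ndarray:
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    return d


def write_distance_matrix(dist: pd.DataFrame, path) -> None:
    out = dist.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_distance_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_distance(df)
    return df


def pcoa(dist: pd.DataFrame, n_axes: int | None = None) -> OrdinationResult:
    """Classical PCoA: Gower double-centering of -d^2/2 then eigendecomposition.

    Axes for negative eigenvalues (non-Euclidean distances) are dropped and
    the negative eigenvalues reported; no Cailliez/Lingoes correction is
    applied. Proportions explained are relative to the positive-eigenvalue
    total.
    """
    d = _check_distance(dist)
    n = d.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    gower = centering @ (-0.5 * d**2) @ centering
    eigvals, eigvecs = np.linalg.eigh((gower + gower.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-8 * max(abs(eigvals).max(), 1.0) if n > 1 else 1e-8
    positive = eigvals > tol
    negative = eigvals[eigvals < -tol]
    kept = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(kept)
    if n_axes is not None:
        if n_axes > kept.size:
            warnings.warn(
                f"requested {n_axes} axes but only {kept.size} positive eigenvalues; truncating",
                stacklevel=2,
            )
        n_axes = min(n_axes, kept.size)
        coords, kept = coords[:, :n_axes], kept[:n_axes]
    proportions = kept / eigvals[positive].sum() if kept.size else kept
    frame = pd.DataFrame(
        coords, index=dist.index, columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]
    )
    return OrdinationResult(frame, kept, proportions, negative)


def _group_codes(grouping: pd.Series, ids) -> np.ndarray:
    grouping = grouping.reindex(ids)
    if grouping.isna().any():
        raise ValueError("grouping missing for some samples")
    return pd.Categorical(grouping).codes.astype(np.intp)


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)][np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(dist: pd.DataFrame, grouping: pd.Series, n_perm=999, seed=None) -> PermTestResult:
    """One-way PERMANOVA (pseudo-F on squared distances, label permutation)."""
    d = _check_distance(dist)
    codes = _group_codes(grouping, dist.index)
    counts = np.bincount(codes)
    if counts.size < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")
    d2 = d**2
    n = d.shape[0]
    f_obs = _pseudo_f(d2, codes, counts.size)
    if n_perm == "exhaustive":
        if n > _EXHAUSTIVE_LIMIT:
            raise ValueError(f"exhaustive enumeration limited to n <= {_EXHAUSTIVE_LIMIT}")
        hits, total = 0, 0
        for perm in itertools.permutations(range(n)):
            f_perm = _pseudo_f(d2, codes[list(perm)], counts.size)
            hits += f_perm >= f_obs - 1e-12
            total += 1
        return PermTestResult(f_obs, hits / total, total - 1, seed, "permanova-exhaustive")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm = _pseudo_f(d2, rng.permutation(codes), counts.size)
        hits += f_perm >= f_obs - 1e-12
    return PermTestResult(f_obs, (1 + hits) / (1 + n_perm), n_perm, seed, "permanova")


def _term_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Dummy-coded columns for a main effect or an `a:b` interaction."""
    parts = term.split(":")
    blocks = []
    for part in parts:
        if part not in metadata.columns:
            raise ValueError(f"unknown factor {part!r}")
        blocks.append(pd.get_dummies(metadata[part].astype("category"), drop_first=True).to_numpy(float))
    out = blocks[0]
    for block in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, block).reshape(out.shape[0], -1)
    return out


def permanova_factorial(
    dist: pd.DataFrame,
    metadata: pd.DataFrame,
    terms,
    n_perm: int = 999,
    seed=None,
) -> pd.DataFrame:
    """Multi-factor PERMANOVA with sequential (Type I) sums of squares.

    Terms are fitted in the given order via hat-matrix projections of the
    Gower-centered matrix (McArdle-Anderson partitioning); permutations
    shuffle raw sample labels. Interactions are written ``"a:b"``.
    """
    d = _check_distance(dist)
    metadata = metadata.reindex(dist.index)
    if metadata.isna().any().any():
        raise ValueError("metadata missing for some samples")
    n = d.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    gower = centering @ (-0.5 * d**2) @ centering

    design = np.ones((n, 1))
    hats, dfs = [], []
    prev_rank = 1
    for term in terms:
        design = np.hstack([design, _term_columns(metadata, term)])
        q, r = np.linalg.qr(design)
        rank = int((np.abs(np.diag(r)) > 1e-10).sum())
        keep = q[:, :rank]
        hats.append(keep @ keep.T)
        dfs.append(rank - prev_rank)
        prev_rank = rank
    df_resid = n - prev_rank
    if df_resid <= 0:
        raise ValueError("model saturated: no residual degrees of freedom")
    full_hat = hats[-1]

    def term_stats(g: np.ndarray):
        ss, prev_hat = [], np.ones((n, n)) / n
        for hat in hats:
            ss.append(np.sum((hat - prev_hat) * g))
            prev_hat = hat
        ss_resid = np.sum((np.eye(n) - full_hat) * g)
        f = [
            (ss_k / df_k) / (ss_resid / df_resid) if df_k else np.nan
            for ss_k, df_k in zip(ss, dfs)
        ]
        return np.asarray(ss), np.asarray(f), ss_resid

    ss_obs, f_obs, ss_resid = term_stats(gower)
    rng = np.random.default_rng(seed)
    hits = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, f_perm, _ = term_stats(gower[np.ix_(perm, perm)])
        hits += f_perm >= f_obs - 1e-12
    p_values = (1 + hits) / (1 + n_perm)
    return pd.DataFrame(
        {"ss": ss_obs, "df": dfs, "pseudo_F": f_obs, "p_value": p_values,
         "ss_residual": ss_resid, "df_residual": df_resid},
        index=list(terms),
    )


def mantel(
    dist_a: pd.DataFrame,
    dist_b: pd.DataFrame,
    n_perm=999,
    seed=None,
) -> PermTestResult:
    """Mantel test: Pearson r between off-diagonal entries, permuting one matrix."""
    if set(dist_a.index) != set(dist_b.index):
        raise ValueError("distance matrices cover different sample sets")
    dist_b = dist_b.reindex(index=dist_a.index, columns=dist_a.index)
    a = _check_distance(dist_a)
    b = _check_distance(dist_b)
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    va, vb = a[iu], b[iu]
    if va.std() == 0 or vb.std() == 0:
        return PermTestResult(0.0, 1.0, 0, seed, "mantel", degenerate=True)

    za = (va - va.mean()) / va.std()
    zb = (vb - vb.mean()) / vb.std()
    r_obs = float(np.mean(za * zb))

    def r_of(perm) -> float:
        bp = b[np.ix_(perm, perm)][iu]
        sd = bp.std()
        if sd == 0:
            return 0.0
        return float(np.mean(za * (bp - bp.mean()) / sd))

    if n_perm == "exhaustive":
        if n > _EXHAUSTIVE_LIMIT:
            raise ValueError(f"exhaustive enumeration limited to n <= {_EXHAUSTIVE_LIMIT}")
        hits, total = 0, 0
        for perm in itertools.permutations(range(n)):
            hits += abs(r_of(list(perm))) >= abs(r_obs) - 1e-12
            total += 1
        return PermTestResult(r_obs, hits / total, total - 1, seed, "mantel-exhaustive")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += abs(r_of(rng.permutation(n))) >= abs(r_obs) - 1e-12
    return PermTestResult(r_obs, (1 + hits) / (1 + n_perm), n_perm, seed, "mantel")
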