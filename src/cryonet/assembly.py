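"""Normalized stochasticity ratio (NST): null-model quantification of assembly.

The stochasticity ratio compares each within-group pair's observed
dissimilarity G with the expectation E of the same dissimilarity under a
null model that preserves per-sample richness and draws occupants with
probability proportional to their occurrence frequency, redistributing the
sample's reads among the drawn taxa in proportion to regional mean relative
abundance. Per pair,

    NST = (1 - G) / (1 - E)   if G >= E      (more divergent than null)
        = G / E               if G <  E      (more similar than null)

clamped to [0, 1]; NST = 1 when observed dissimilarity coincides with the
null expectation (assembly indistinguishable from stochastic), and 0 at
either extreme (identical communities, or maximal divergence). A group's NST
is the mean pairwise NST expressed in percent: > 50% is read as
stochastic-dominated assembly, < 50% deterministic-dominated.

The default dissimilarity is Ruzicka (abundance-based Jaccard); binary
Jaccard is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist, pdist, squareform

from .community import PermTestResult

__all__ = [
    "NullModelSpec",
    "NstResult",
    "ruzicka_matrix",
    "jaccard_matrix",
    "null_draw",
    "pairwise_nst",
    "nst_compare",
]


@dataclass(frozen=True)
class NullModelSpec:
    """Null-model configuration; ``n_draws >= 100`` recommended for reported results."""

    algorithm: str = "richness-and-frequency-proportional"
    n_draws: int = 1000
    metric: str = "ruzicka"
    seed: int = 0

    def __post_init__(self):
        if self.algorithm != "richness-and-frequency-proportional":
            raise ValueError(f"unknown null algorithm {self.algorithm!r}")
        if self.metric not in {"ruzicka", "jaccard"}:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.n_draws < 1:
            raise ValueError("n_draws must be positive")


@dataclass
class NstResult:
    group: str
    pairwise: pd.DataFrame  # sample_a, sample_b, g_obs, e_null, st, nst, degenerate
    group_nst: float  # percent
    spec: NullModelSpec = field(default_factory=NullModelSpec)

    def to_files(self, pairwise_path, summary_path=None) -> None:
        self.pairwise.to_csv(pairwise_path, sep="\t", index=False, float_format="%.10g")
        if summary_path is not None:
            import dataclasses
            import json

            doc = {
                "group": self.group,
                "group_nst_percent": self.group_nst,
                "n_pairs": int(self.pairwise.shape[0]),
                "null_spec": dataclasses.asdict(self.spec),
            }
            with open(summary_path, "w") as fh:
                json.dump(doc, fh, indent=1, sort_keys=True)


def ruzicka_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise Ruzicka dissimilarity 1 - sum(min)/sum(max) on abundances."""
    x = np.asarray(x, dtype=float)
    l1 = cdist(x, x, metric="cityblock")
    totals = x.sum(axis=1)
    grand = totals[:, None] + totals[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(grand + l1 > 0, 2.0 * l1 / (grand + l1), 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def jaccard_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise binary Jaccard dissimilarity on presence/absence."""
    b = np.asarray(x) > 0
    if b.shape[0] < 2:
        return np.zeros((b.shape[0], b.shape[0]))
    return squareform(pdist(b, metric="jaccard"))


_METRICS = {"ruzicka": ruzicka_matrix, "jaccard": jaccard_matrix}


def null_draw(table: pd.DataFrame, spec: NullModelSpec, draw_index: int) -> pd.DataFrame:
    """One null community table constrained to observed per-sample richness.

    Occupants are drawn without replacement with probability proportional to
    occurrence frequency in the regional pool (the input table); each drawn
    taxon receives one read, and the remainder of the sample's total is
    redistributed multinomially in proportion to regional mean relative
    abundance, so richness is preserved exactly. Deterministic given
    ``(spec.seed, draw_index)``.
    """
    x = table.to_numpy(dtype=np.int64)
    n_samples, n_taxa = x.shape
    rng = np.random.default_rng([int(spec.seed), int(draw_index)])
    freq = (x > 0).mean(axis=0)
    rel = x / x.sum(axis=1, keepdims=True)
    regional = rel.mean(axis=0)
    candidates = np.flatnonzero(freq > 0)
    probs = freq[candidates] / freq[candidates].sum()
    out = np.zeros_like(x)
    for i in range(n_samples):
        s = int((x[i] > 0).sum())
        total = int(x[i].sum())
        if s == 0:
            continue
        chosen = rng.choice(candidates, size=s, replace=False, p=probs)
        out[i, chosen] = 1
        weights = regional[chosen]
        weights = weights / weights.sum() if weights.sum() > 0 else np.full(s, 1.0 / s)
        out[i, chosen] += rng.multinomial(total - s, weights)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def _nst_value(g: float, e: float):
    """Pairwise NST with degenerate-null guards; returns (nst, degenerate)."""
    if np.isclose(g, e, atol=1e-12):
        return 1.0, False
    if e <= 0.0:
        return 0.0, True  # null expects identity but observation diverges
    if g >= e:
        if e >= 1.0:
            return 0.0, True  # null expects maximal divergence; symmetric guard
        nst = (1.0 - g) / (1.0 - e)
    else:
        nst = g / e
    return float(min(max(nst, 0.0), 1.0)), False


def pairwise_nst(table: pd.DataFrame, groups: pd.Series, spec: NullModelSpec) -> dict:
    """Per-group pairwise and mean NST; the group's sub-table is its regional pool.

    ``groups`` maps sample id to a group label; every group needs >= 2
    samples. Returns ``{label: NstResult}``; ``group_nst`` is in percent.
    """
    groups = groups.reindex(table.index)
    if groups.isna().any():
        raise ValueError("grouping missing for some samples")
    metric = _METRICS[spec.metric]
    results = {}
    for label in groups.unique():
        ids = table.index[groups == label]
        if len(ids) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
        sub = table.loc[ids]
        g_mat = metric(sub.to_numpy())
        e_mat = np.zeros_like(g_mat)
        for k in range(spec.n_draws):
            e_mat += metric(null_draw(sub, spec, k).to_numpy())
        e_mat /= spec.n_draws
        rows = []
        iu = np.triu_indices(len(ids), 1)
        for i, j in zip(*iu):
            g_obs, e_null = float(g_mat[i, j]), float(e_mat[i, j])
            nst, degenerate = _nst_value(g_obs, e_null)
            st = min(g_obs, e_null) / max(g_obs, e_null) if max(g_obs, e_null) > 0 else 1.0
            rows.append(
                {
                    "sample_a": ids[i],
                    "sample_b": ids[j],
                    "g_obs": g_obs,
                    "e_null": e_null,
                    "st": st,
                    "nst": nst,
                    "degenerate": degenerate,
                }
            )
        pairwise = pd.DataFrame(rows)
        results[label] = NstResult(
            group=str(label),
            pairwise=pairwise,
            group_nst=float(pairwise["nst"].mean() * 100.0),
            spec=spec,
        )
    return results


def nst_compare(
    result_a: NstResult,
    result_b: NstResult,
    n_boot: int = 999,
    seed=None,
    method: str = "t",
) -> PermTestResult:
    """Two-sided comparison of group NST on the pairwise NST values.

    ``method="t"`` is a Welch t-test (how per-panel NST contrasts are usually
    annotated); ``method="bootstrap"`` resamples pairs within each group and
    inverts the bootstrap distribution of the mean difference.
    """
    if result_a.spec != result_b.spec:
        raise ValueError("results were computed under different null specs")
    a = result_a.pairwise["nst"].to_numpy()
    b = result_b.pairwise["nst"].to_numpy()
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 pairs per group")
    diff = float(a.mean() - b.mean())
    if method == "t":
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p = 1.0 if np.isclose(diff, 0) else 0.0
            return PermTestResult(diff, p, 0, seed, "nst-t", degenerate=True)
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        return PermTestResult(float(stat), float(p), 0, seed, "nst-t")
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for k in range(n_boot):
            boots[k] = (
                rng.choice(a, size=a.size, replace=True).mean()
                - rng.choice(b, size=b.size, replace=True).mean()
            )
        frac = (1 + np.sum(boots <= 0)) / (1 + n_boot)
        p = float(2 * min(frac, 1 - frac + 1 / (1 + n_boot)))
        return PermTestResult(diff, min(p, 1.0), n_boot, seed, "nst-bootstrap")
    raise ValueError(f"unknown method {method!r}")
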