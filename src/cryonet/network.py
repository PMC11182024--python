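"""Co-occurrence network construction, modules, node roles and stability.

Networks are undirected ``networkx.Graph`` objects over taxon ids. Every edge
carries the correlation evidence that created it (``rho``, ``p_adj`` and
``sign``); the build thresholds are stored as graph attributes. The default
thresholds follow the usual soil-network recipe: Spearman correlation,
Benjamini-Hochberg FDR correction, keep |rho| >= 0.6 and adjusted P <= 0.01.

Node roles follow the Guimera-Amaral topological classification: Zi is the
within-module degree z-score, Pi the among-module (participation)
connectivity; nodes with Zi > 2.5 or Pi > 0.625 are flagged as keystones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import relative_abundance

__all__ = [
    "ModulePartition",
    "PNRatio",
    "correlation_matrix",
    "bh_adjust",
    "bh_adjust_matrix",
    "build_network",
    "build_cooccurrence_network",
    "detect_modules",
    "zipi",
    "robustness",
    "connectedness",
    "pn_ratio",
    "subnetwork",
    "module_abundance",
    "write_edge_list",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.625


@dataclass
class ModulePartition:
    """Node -> module id (1 = largest module) plus the modularity score."""

    membership: dict
    modularity: float
    sizes: dict = field(default_factory=dict)

    def members(self, module_id: int) -> list:
        return sorted(n for n, m in self.membership.items() if m == module_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": list(self.membership), "module": list(self.membership.values())}
        ).sort_values(["module", "node"], ignore_index=True)


@dataclass(frozen=True)
class PNRatio:
    n_positive: int
    n_negative: int
    ratio: float  # nan when undefined
    defined: bool


def correlation_matrix(table: pd.DataFrame, method: str = "spearman"):
    """Pairwise taxon-taxon correlation and two-sided p matrices.

    Spearman uses average ranks for ties and the t approximation for p.
    Constant taxa have undefined correlation; their entries are recorded as
    rho = 0 with p = 1 (flagged via a warning).
    """
    if table.shape[0] < 4:
        raise ValueError("need at least 4 samples for correlation inference")
    x = table.to_numpy(dtype=float)
    if method != "spearman":
        raise ValueError(f"unsupported method {method!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, p = stats.spearmanr(x, axis=0)
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if rho.shape == (1, 1):  # two taxa: spearmanr returns scalars
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
        q = float(p[0, 0])
        p = np.array([[0.0, q], [q, 0.0]])
    constant = x.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant taxa: correlations recorded as 0 (p=1)",
            stacklevel=2,
        )
    bad = ~np.isfinite(rho)
    rho[bad] = 0.0
    p[bad | ~np.isfinite(p)] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    ids = table.columns
    return (
        pd.DataFrame(rho, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, rank-monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p.ravel(), method="bh").reshape(p.shape)


def bh_adjust_matrix(p: pd.DataFrame) -> pd.DataFrame:
    """BH-adjust the upper-triangle p-values of a symmetric matrix in place."""
    values = p.to_numpy(dtype=float).copy()
    iu = np.triu_indices(values.shape[0], 1)
    values[iu] = bh_adjust(values[iu])
    values.T[iu] = values[iu]
    return pd.DataFrame(values, index=p.index, columns=p.columns)


def build_network(
    rho: pd.DataFrame,
    p_adj: pd.DataFrame,
    r_min: float = 0.6,
    p_max: float = 0.01,
) -> nx.Graph:
    """Keep an edge iff |rho| >= r_min and adjusted p <= p_max; isolated nodes stay.

    The magnitude convention means strong *negative* correlations also become
    edges (with ``sign="-"``), which the positive/negative link-ratio
    analysis requires.
    """
    if not 0 < r_min <= 1:
        raise ValueError("r_min must lie in (0, 1]")
    if not (rho.index.equals(p_adj.index) and rho.columns.equals(p_adj.columns)):
        raise ValueError("rho and p matrices must share taxa")
    taxa = list(rho.index)
    graph = nx.Graph(r_min=float(r_min), p_max=float(p_max))
    graph.add_nodes_from(taxa)
    r = rho.to_numpy(dtype=float)
    q = p_adj.to_numpy(dtype=float)
    iu = np.triu_indices(len(taxa), 1)
    keep = (np.abs(r[iu]) >= r_min) & (q[iu] <= p_max)
    for i, j in zip(iu[0][keep], iu[1][keep]):
        graph.add_edge(
            taxa[i],
            taxa[j],
            rho=float(r[i, j]),
            p_adj=float(q[i, j]),
            sign="+" if r[i, j] > 0 else "-",
        )
    return graph


def build_cooccurrence_network(
    table: pd.DataFrame,
    r_min: float = 0.6,
    p_max: float = 0.01,
) -> nx.Graph:
    """Correlate -> FDR-adjust -> threshold, on an already prevalence-filtered table."""
    rho, p = correlation_matrix(table)
    return build_network(rho, bh_adjust_matrix(p), r_min=r_min, p_max=p_max)


def detect_modules(network: nx.Graph, seed=None, resolution: float = 1.0) -> ModulePartition:
    """Greedy (fast-greedy) modularity optimization on the unsigned graph.

    Module ids are assigned by descending size (ties broken by smallest node
    label) so Module #1 is always the largest. The algorithm is
    deterministic; ``seed`` is accepted for interface symmetry.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if network.number_of_edges() == 0:
        communities = [{n} for n in sorted(network.nodes)]
        score = 0.0
    else:
        communities = [
            set(c)
            for c in nx.community.greedy_modularity_communities(network, resolution=resolution)
        ]
        score = nx.community.modularity(network, communities)
    communities.sort(key=lambda c: (-len(c), min(c)))
    membership = {}
    sizes = {}
    for module_id, members in enumerate(communities, start=1):
        sizes[module_id] = len(members)
        for node in members:
            membership[node] = module_id
    return ModulePartition(membership=membership, modularity=float(score), sizes=sizes)


def zipi(
    network: nx.Graph,
    partition: ModulePartition,
    zi_threshold: float = ZI_THRESHOLD,
    pi_threshold: float = PI_THRESHOLD,
) -> pd.DataFrame:
    """Guimera-Amaral Zi/Pi role scores and keystone flags per node.

    Zi = (within-module degree - module mean) / module sd (0 if sd = 0);
    Pi = 1 - sum_s (k_is / k_i)^2 with Pi = 0 for isolated nodes. Roles:
    peripheral, module-hub (Zi high), connector (Pi high), network-hub (both).
    """
    missing = set(network.nodes) - set(partition.membership)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    nodes = sorted(network.nodes)
    within = {}
    for node in nodes:
        own = partition.membership[node]
        within[node] = sum(
            1 for nb in network.neighbors(node) if partition.membership[nb] == own
        )
    by_module = {}
    for node in nodes:
        by_module.setdefault(partition.membership[node], []).append(within[node])
    module_stats = {
        m: (float(np.mean(v)), float(np.std(v))) for m, v in by_module.items()
    }
    rows = []
    for node in nodes:
        degree = network.degree(node)
        mean, sd = module_stats[partition.membership[node]]
        zi = (within[node] - mean) / sd if sd > 0 else 0.0
        if degree == 0:
            pi = 0.0
        else:
            counts = {}
            for nb in network.neighbors(node):
                m = partition.membership[nb]
                counts[m] = counts.get(m, 0) + 1
            pi = 1.0 - sum((k / degree) ** 2 for k in counts.values())
        hub = zi > zi_threshold
        connector = pi > pi_threshold
        role = (
            "network-hub" if hub and connector
            else "module-hub" if hub
            else "connector" if connector
            else "peripheral"
        )
        rows.append(
            {
                "node": node,
                "module": partition.membership[node],
                "degree": degree,
                "zi": zi,
                "pi": pi,
                "role": role,
                "keystone": hub or connector,
            }
        )
    return pd.DataFrame(rows).set_index("node")


def robustness(
    network: nx.Graph,
    removal_fraction: float = 0.5,
    trials: int = 100,
    seed=None,
) -> float:
    """Mean fraction of nodes keeping >= 1 link after random node removal.

    In each trial ``floor(removal_fraction * N)`` nodes are removed uniformly
    at random; the survivors with at least one remaining link are counted and
    divided by the original N.
    """
    if not 0 < removal_fraction < 1:
        raise ValueError("removal_fraction must lie in (0, 1)")
    nodes = sorted(network.nodes)
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    adjacency = nx.to_numpy_array(network, nodelist=nodes, weight=None).astype(bool)
    n_remove = int(np.floor(removal_fraction * n))
    rng = np.random.default_rng(seed)
    fractions = np.empty(trials)
    for t in range(trials):
        keep = np.ones(n, dtype=bool)
        keep[rng.choice(n, size=n_remove, replace=False)] = False
        sub = adjacency[np.ix_(keep, keep)]
        fractions[t] = (sub.sum(axis=1) >= 1).sum() / n
    return float(fractions.mean())


def connectedness(network: nx.Graph, method: str = "pair_fraction") -> float:
    """Fraction of node pairs in the same component (or largest-component share)."""
    n = network.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    sizes = [len(c) for c in nx.connected_components(network)]
    if method == "pair_fraction":
        return float(sum(s * (s - 1) for s in sizes) / (n * (n - 1)))
    if method == "largest_component":
        return float(max(sizes) / n)
    raise ValueError(f"unknown method {method!r}")


def pn_ratio(network: nx.Graph) -> PNRatio:
    """Positive / negative edge-count ratio; undefined when no negative edges."""
    signs = [data.get("sign", "+") for _, _, data in network.edges(data=True)]
    n_pos = sum(s == "+" for s in signs)
    n_neg = len(signs) - n_pos
    if n_neg == 0:
        return PNRatio(n_pos, 0, float("nan"), defined=False)
    return PNRatio(n_pos, n_neg, n_pos / n_neg, defined=True)


def subnetwork(network: nx.Graph, table: pd.DataFrame, sample_subset) -> nx.Graph:
    """Induced subgraph on taxa present (count > 0) in >= 1 subset sample."""
    sample_subset = list(sample_subset)
    if not sample_subset:
        raise ValueError("sample_subset is empty")
    unknown = [s for s in sample_subset if s not in table.index]
    if unknown:
        raise KeyError(f"unknown samples: {unknown}")
    present = set(table.columns[(table.loc[sample_subset] > 0).any(axis=0)])
    nodes = [n for n in network.nodes if n in present]
    sub = network.subgraph(nodes).copy()
    sub.graph.update(network.graph)
    return sub


def module_abundance(
    table: pd.DataFrame,
    partition: ModulePartition,
    modules=None,
) -> pd.DataFrame:
    """Per-sample summed relative abundance of each module, z-scored over samples.

    Degenerate modules (zero variance across samples) give NaN columns with a
    warning. ``modules`` restricts to specific module ids (default: all).
    """
    rel = relative_abundance(table)
    module_ids = sorted(set(partition.membership.values())) if modules is None else list(modules)
    out = {}
    for module_id in module_ids:
        members = [t for t in partition.members(module_id) if t in table.columns]
        if not members:
            raise ValueError(f"module {module_id} has no taxa in the table")
        raw = rel[members].sum(axis=1)
        sd = raw.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            warnings.warn(f"module {module_id} abundance is constant; z undefined", stacklevel=2)
            out[f"Module_{module_id}"] = pd.Series(np.nan, index=table.index)
        else:
            out[f"Module_{module_id}"] = (raw - raw.mean()) / sd
    return pd.DataFrame(out)


def write_edge_list(network: nx.Graph, path) -> None:
    """Serialize edges as node_a / node_b / rho / p_adj / sign TSV (sorted, deterministic)."""
    rows = [
        {
            "node_a": min(a, b),
            "node_b": max(a, b),
            "rho": data.get("rho", np.nan),
            "p_adj": data.get("p_adj", np.nan),
            "sign": data.get("sign", "+"),
        }
        for a, b, data in network.edges(data=True)
    ]
    frame = pd.DataFrame(rows, columns=["node_a", "node_b", "rho", "p_adj", "sign"])
    if not frame.empty:
        frame = frame.sort_values(["node_a", "node_b"], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
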