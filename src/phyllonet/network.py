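"""Co-abundance networks, complexity metrics, and community cohesion.

A network per (time point, compartment) stratum keeps an edge between two
OTUs when its bootstrap pseudo p-value is at most ``p_max`` (0.001 by
default) and the correlation is non-zero; edge weight is the SparCC rho and
the sign marks putative positive vs negative interaction.  Isolated OTUs are
dropped, so node counts refer to connected OTUs (edge-list semantics).

Cohesion quantifies per-sample connectivity: for each OTU, its positive
(negative) connectivity is the mean of its significant positive (negative)
correlations; a sample's positive (negative) cohesion is the relative-
abundance-weighted sum of these connectivities, and total cohesion is the
positive part plus the absolute negative part.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .sparcc import SparCCResults

__all__ = [
    "CoNetwork",
    "build_network",
    "network_complexity",
    "inherited_nodes",
    "connectivity_values",
    "cohesion",
    "CohesionResult",
    "complexity_env_correlation",
    "cohesion_env_correlation",
]


class NetworkError(ValueError):
    pass


@dataclass
class CoNetwork:
    """Signed, weighted, undirected co-abundance graph for one stratum."""

    graph: nx.Graph
    stratum: tuple | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> pd.DataFrame:
        rows = [
            (
                u,
                v,
                d["weight"],
                d["sign"],
                d["p"],
                self.stratum[0] if self.stratum else None,
                self.stratum[1] if self.stratum else None,
            )
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows,
            columns=["source", "target", "rho", "sign", "p", "timepoint", "compartment"],
        )

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    @classmethod
    def read_graphml(cls, path, stratum=None) -> "CoNetwork":
        return cls(nx.read_graphml(path), stratum=stratum)


def build_network(
    result: SparCCResults, p_max: float = 0.001, stratum: tuple | None = None
) -> CoNetwork:
    """Edges for OTU pairs with p <= p_max and |rho| > 0; isolated OTUs dropped."""
    if result.pvalues is None:
        raise NetworkError("SparCC results carry no p-values; fit with bootstraps")
    if list(result.rho.index) != list(result.pvalues.index) or list(
        result.rho.columns
    ) != list(result.pvalues.columns):
        raise NetworkError("rho and pvalue matrices have mismatched OTU ids")
    g = nx.Graph()
    for _, row in result.significant_pairs(p_max=p_max).iterrows():
        g.add_edge(
            row["otu_a"],
            row["otu_b"],
            weight=float(row["rho"]),
            sign="+" if row["rho"] > 0 else "-",
            p=float(row["p"]),
        )
    return CoNetwork(g, stratum=stratum)


def network_complexity(net: CoNetwork) -> tuple[int, int, float]:
    """(n_nodes, n_edges, positive-edge fraction); fraction is NaN if empty."""
    n_edges = net.n_edges
    if n_edges == 0:
        return (0, 0, float("nan"))
    pos = sum(1 for _, _, d in net.graph.edges(data=True) if d["weight"] > 0)
    return (net.n_nodes, n_edges, pos / n_edges)


def inherited_nodes(net_a: CoNetwork, net_b: CoNetwork) -> set:
    """OTUs present in both networks (conserved between consecutive times)."""
    return set(net_a.graph.nodes) & set(net_b.graph.nodes)


def connectivity_values(result: SparCCResults, p_max: float = 0.001) -> pd.DataFrame:
    """Per-OTU mean significant positive and negative correlations.

    An OTU with no significant positive (negative) partner gets positive
    (negative) connectivity 0, so the values lie in [0, 1] and [-1, 0].
    """
    if result.pvalues is None:
        raise NetworkError("SparCC results carry no p-values; fit with bootstraps")
    ids = result.otu_ids
    r = result.rho.to_numpy().copy()
    p = result.pvalues.to_numpy()
    np.fill_diagonal(r, 0.0)
    sig = (p <= p_max) & (np.abs(r) > 0)
    np.fill_diagonal(sig, False)
    pos = np.where(sig & (r > 0), r, np.nan)
    neg = np.where(sig & (r < 0), r, np.nan)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        # OTUs without significant partners produce all-NaN rows by design
        _warnings.simplefilter("ignore", RuntimeWarning)
        pos_conn = np.nan_to_num(np.nanmean(pos, axis=1))
        neg_conn = np.nan_to_num(np.nanmean(neg, axis=1))
    return pd.DataFrame(
        {"positive": pos_conn, "negative": neg_conn}, index=pd.Index(ids, name="otu")
    )


@dataclass
class CohesionResult:
    """Per-sample positive, negative and total cohesion.

    ``samples`` has columns positive (in [0, 1]), negative (in [-1, 0]) and
    total = positive + |negative| (in [0, 2]); ``connectivity`` is the
    per-OTU table the cohesion was built from.
    """

    samples: pd.DataFrame
    connectivity: pd.DataFrame

    def __post_init__(self) -> None:
        s = self.samples
        eps = 1e-9
        assert (s["positive"] >= -eps).all() and (s["positive"] <= 1 + eps).all()
        assert (s["negative"] <= eps).all() and (s["negative"] >= -1 - eps).all()
        assert (s["total"] >= -eps).all() and (s["total"] <= 2 + eps).all()

    @property
    def total(self) -> pd.Series:
        return self.samples["total"]

    def summary(self) -> str:
        d = self.samples.describe().loc[["mean", "std", "min", "max"]]
        return "Cohesion per sample\n" + d.to_string(float_format=lambda x: f"{x:.4f}")

    def write_tsv(self, path) -> None:
        self.samples.rename_axis("sample").to_csv(path, sep="\t")


def cohesion(ra_table: pd.DataFrame, connectivity: pd.DataFrame) -> CohesionResult:
    """Relative-abundance-weighted connectivity per sample.

    ``ra_table`` is OTU x sample relative abundances over the
    network-filtered OTU set (columns summing to at most 1);
    ``connectivity`` is the output of :func:`connectivity_values` on the same
    OTUs.  Positive cohesion_j = sum_i RA_ij * positive-connectivity_i, the
    negative analogue likewise, and total = positive + |negative|.
    """
    if set(ra_table.index) != set(connectivity.index):
        missing = set(ra_table.index) ^ set(connectivity.index)
        raise NetworkError(
            f"RA table and connectivity cover different OTUs ({sorted(missing)[:5]} ...)"
        )
    conn = connectivity.loc[ra_table.index]
    ra = ra_table.to_numpy(dtype=float)
    col_sums = ra.sum(axis=0)
    if (col_sums > 1.0 + 1e-9).any():
        raise NetworkError("relative abundances must sum to <= 1 per sample")
    pos = ra.T @ conn["positive"].to_numpy()
    neg = ra.T @ conn["negative"].to_numpy()
    samples = pd.DataFrame(
        {"positive": pos, "negative": neg, "total": pos + np.abs(neg)},
        index=ra_table.columns,
    )
    return CohesionResult(samples, conn)


def complexity_env_correlation(
    complexity_per_timepoint: pd.DataFrame, env_per_timepoint: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r of node counts against each factor across time points.

    ``complexity_per_timepoint`` is indexed by time point with an
    ``n_nodes`` column; ``env_per_timepoint`` is time point x factor (e.g.
    cross-site monthly means).  Constant inputs yield NaN r and p.
    """
    joined = complexity_per_timepoint.join(env_per_timepoint, how="inner")
    y = joined["n_nodes"].to_numpy(dtype=float)
    rows = []
    for factor in env_per_timepoint.columns:
        x = joined[factor].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((factor, float("nan"), float("nan")))
        else:
            r, p = pearsonr(y, x)
            rows.append((factor, r, p))
    return pd.DataFrame(rows, columns=["factor", "r", "p"]).set_index("factor")


def cohesion_env_correlation(
    total_cohesion: pd.Series, env_aligned: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rho of per-sample total cohesion against each factor."""
    env = env_aligned.loc[total_cohesion.index]
    y = total_cohesion.to_numpy()
    rows = []
    for factor in env.columns:
        x = env[factor].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((factor, float("nan"), float("nan")))
            continue
        rho, p = spearmanr(y, x)
        rows.append((factor, rho, p))
    return pd.DataFrame(rows, columns=["factor", "rho", "p"]).set_index("factor")
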