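"""Hypergeometric pathway over-representation and the pathway-overlap network.

For a query gene set of size n drawn from a universe of N genes (the
expressed genes on the platform by default), the over-representation p-value
of a pathway with K members in the universe and k members in the query is the
hypergeometric upper tail P(X >= k).  Pathways passing a raw p cutoff
(default 0.001) form a network in which nodes carry the overlap size and
p-value and edges the number of query genes shared between two pathways.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import GeneSet
from .errors import MirpullError, ParseError

logger = logging.getLogger(__name__)

DEFAULT_P_CUT = 1e-3


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    members: frozenset


@dataclass
class PathwayCollection:
    """A GMT-style collection of pathways with a gene universe."""

    pathways: dict[str, Pathway]
    universe: frozenset

    def __len__(self) -> int:
        return len(self.pathways)

    @classmethod
    def from_gmt(cls, path, universe: frozenset | None = None) -> "PathwayCollection":
        """Read GMT (tab-separated: id, description, member genes...).

        When no universe is given, the union of all pathway members is used.
        """
        pathways: dict[str, Pathway] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\r\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: GMT line needs id, description and "
                        f">=1 gene; got {len(parts)} fields"
                    )
                pid, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
                if pid in pathways:
                    raise ParseError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
                pathways[pid] = Pathway(pid, name, frozenset(genes))
        if universe is None:
            universe = frozenset().union(*(p.members for p in pathways.values()))
        return cls(pathways=pathways, universe=frozenset(universe))

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for pid in sorted(self.pathways):
                p = self.pathways[pid]
                fh.write("\t".join([p.pathway_id, p.name, *sorted(p.members)]) + "\n")


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: pathway size, n: query size, k: overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise MirpullError(f"inconsistent margins: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise MirpullError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: GeneSet,
    pathways: PathwayCollection,
    p_cut: float = DEFAULT_P_CUT,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query in every pathway.

    Pathway members and the query are intersected with the universe first;
    pathways empty after intersection are dropped with a warning.  Returns a
    frame sorted by p with columns pathway_id, name, k, K, n, N, p, bh_q,
    significant (raw p < p_cut; bh_q is informational only).
    """
    universe = pathways.universe
    outside = query.members - universe
    if outside:
        warnings.warn(
            f"query {query.label!r}: {len(outside)} gene(s) outside the "
            "universe dropped"
        )
    q = query.members & universe
    if not q:
        raise MirpullError(f"query {query.label!r} empty after universe intersection")
    N, n = len(universe), len(q)
    rows = []
    for pid in sorted(pathways.pathways):
        p_obj = pathways.pathways[pid]
        members = p_obj.members & universe
        if not members:
            warnings.warn(f"pathway {pid!r} empty after universe intersection; dropped")
            continue
        K = len(members)
        k = len(members & q)
        rows.append(
            {"pathway_id": pid, "name": p_obj.name, "k": k, "K": K, "n": n, "N": N,
             "p": hypergeom_p(k, K, n, N)}
        )
    frame = pd.DataFrame(rows)
    # Benjamini-Hochberg, informational only (hit filtering uses raw p)
    m = len(frame)
    sorted_idx = frame["p"].sort_values(kind="mergesort").index
    q = frame.loc[sorted_idx, "p"].to_numpy() * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    frame.loc[sorted_idx, "bh_q"] = np.clip(q, 0.0, 1.0)
    frame["significant"] = frame["p"] < p_cut
    return frame.sort_values(["p", "pathway_id"]).reset_index(drop=True)


def build_network(
    results: pd.DataFrame,
    query: GeneSet,
    pathways: PathwayCollection,
    p_cut: float = DEFAULT_P_CUT,
    keep_nonsignificant: bool = False,
    full_membership: bool = False,
) -> nx.Graph:
    """Pathway-overlap network of enriched pathways.

    Nodes are pathways with p < p_cut (all pathways when
    ``keep_nonsignificant``, flagged via the ``significant`` attribute);
    node attributes: ``size`` (= k, query genes in the pathway), ``p``,
    ``significant``.  Edge weight ``shared`` counts genes in both pathways'
    query overlaps (or full membership overlaps with ``full_membership``);
    zero-weight edges are omitted.
    """
    universe = pathways.universe
    q = query.members & universe
    g = nx.Graph()
    kept = results[results["p"] < p_cut] if not keep_nonsignificant else results
    overlaps = {}
    for _, row in kept.iterrows():
        pid = row["pathway_id"]
        members = pathways.pathways[pid].members & universe
        overlaps[pid] = members if full_membership else (members & q)
        g.add_node(
            pid,
            size=int(row["k"]),
            p=float(row["p"]),
            significant=bool(row["p"] < p_cut),
        )
    ids = sorted(overlaps)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            shared = len(overlaps[a] & overlaps[b])
            if shared >= 1:
                g.add_edge(a, b, shared=shared)
    return g


def write_sif(graph: nx.Graph, path) -> None:
    """SIF-style edge list: source <tab> shared_count <tab> target."""
    with open(path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{data['shared']}\t{b}\n")
        for node in sorted(graph.nodes):
            if graph.degree(node) == 0:
                fh.write(f"{node}\n")


def write_node_attributes(graph: nx.Graph, path) -> None:
    rows = [
        {"pathway_id": node, **data} for node, data in sorted(graph.nodes(data=True))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
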