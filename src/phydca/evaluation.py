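"""Benchmarking of ranked pair predictions and signed-network analysis.

Positive-predictive-value curves, per-bin category enrichment, comparison
of competing top-k prediction sets, an operational significance threshold
read off the ranked couplings, and structural analysis (triangle census,
correlation decay with network distance) of the sparse signed network
obtained by thresholding |J|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .baselines import PairScoreList
from .couplings import CouplingModel
from .profiles import ProfileMatrix
from .relations import RelationSet

logger = logging.getLogger(__name__)

__all__ = [
    "SignedNetwork",
    "ppv_curve",
    "enrichment_bins",
    "compare_prediction_sets",
    "significance_threshold",
    "build_signed_network",
    "triangle_census",
    "correlation_vs_distance",
]


@dataclass(frozen=True)
class SignedNetwork:
    """Sparse signed graph of couplings exceeding a |J| threshold.

    ``graph`` is a simple undirected networkx graph whose edges carry
    ``weight`` (the coupling J_ij) and ``sign`` (+1/-1) attributes; every
    edge satisfies |weight| >= threshold.
    """

    graph: nx.Graph
    threshold: float

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError("self-loop in signed network")
            if abs(data["weight"]) < self.threshold:
                raise ValueError(
                    f"edge ({u}, {v}) below threshold {self.threshold}")

    @property
    def n_positive(self) -> int:
        return sum(1 for *_, d in self.graph.edges(data=True)
                   if d["sign"] > 0)

    @property
    def n_negative(self) -> int:
        return sum(1 for *_, d in self.graph.edges(data=True)
                   if d["sign"] < 0)


def ppv_curve(predictions: PairScoreList, positives: RelationSet,
              k_max: int) -> np.ndarray:
    """Positive predictive value among the top-k predictions, k = 1..k_max.

    PPV(k) = |{first k pairs} ∩ positives| / k.  Returns an array of shape
    (k_max, 2) with columns (k, PPV).  An empty positive set yields an
    all-zero curve and a warning.
    """
    if k_max > len(predictions):
        raise ValueError(f"k_max={k_max} exceeds {len(predictions)} predictions")
    if len(positives) == 0:
        logger.warning("empty positive set: PPV curve is identically zero")
    hits = np.fromiter(((i, j) in positives
                        for i, j, _ in predictions.pairs[:k_max]),
                       dtype=np.float64, count=k_max)
    k = np.arange(1, k_max + 1)
    return np.column_stack([k, np.cumsum(hits) / k])


def enrichment_bins(predictions: PairScoreList,
                    category_sets: Mapping[str, RelationSet],
                    bin_size: int = 100) -> dict[str, np.ndarray]:
    """Category membership counts in consecutive bins of ranked pairs.

    For each bin of ``bin_size`` consecutive predictions (last bin may be
    shorter), counts how many pairs belong to each category.  Categories
    are counted independently, so a pair in several categories contributes
    to each and per-bin sums may exceed the bin size.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n_bins = -(-len(predictions) // bin_size)
    out = {}
    for name, rs in category_sets.items():
        counts = np.zeros(n_bins, dtype=np.int64)
        for rank, (i, j, _) in enumerate(predictions.pairs):
            if (i, j) in rs:
                counts[rank // bin_size] += 1
        out[name] = counts
    return out


def compare_prediction_sets(sets: Mapping[str, set[tuple[str, str]]],
                            positives: RelationSet) -> list[dict]:
    """Region table over the membership patterns of 2-3 prediction sets.

    Each row describes one pattern over the named sets, with entries
    "YES" (member), "NO" (non-member) or "-" (either); rows report the
    number of pairs in the union of all sets matching the pattern, the
    true positives among them, and the resulting PPV.  Patterns with "-"
    aggregate the corresponding fully specified rows, so e.g.
    (YES, -) = (YES, YES) + (YES, NO).
    """
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("compare_prediction_sets expects 2 or 3 sets")
    universe = set().union(*sets.values())
    rows = []
    for pattern in product(("YES", "NO", "-"), repeat=len(names)):
        members = [p for p in universe
                   if all(flag == "-" or (p in sets[nm]) == (flag == "YES")
                          for nm, flag in zip(names, pattern))]
        tp = sum(1 for p in members if p in positives)
        rows.append({
            "pattern": dict(zip(names, pattern)),
            "count": len(members),
            "true_positives": tp,
            "ppv": tp / len(members) if members else float("nan"),
        })
    return rows


def significance_threshold(model: CouplingModel, positives: RelationSet,
                           window: int = 100) -> dict:
    """Operational coupling-significance threshold from the ranked tail.

    Couplings are ranked descending; for each rank r the local PPV is the
    fraction of known positives in a centered window of ``window`` ranked
    pairs around r.  The returned threshold is the coupling value at the
    deepest rank down to which the local PPV has stayed >= 0.5, i.e. the
    smallest J above which known relations still dominate.  Returns a dict
    with keys ``threshold`` (float or None), ``rank`` (int or None) and
    ``histograms`` (coupling values of all pairs and of positive pairs,
    for overlay plots).  If even the top window is positive-poor the
    threshold is None.
    """
    if len(positives) == 0:
        raise ValueError("positive set is empty")
    ids = model.domain_ids
    triples = [(ids[a], ids[b], model.J[a, b])
               for a in range(len(ids)) for b in range(a + 1, len(ids))]
    triples.sort(key=lambda t: (-t[2], t[0], t[1]))
    scores = np.array([t[2] for t in triples])
    hits = np.array([(i, j) in positives for i, j, _ in triples], dtype=bool)
    n = len(triples)
    half_lo, half_hi = window // 2 - 1, window // 2
    deepest = None
    for r in range(n):
        lo = max(0, r - half_lo)
        hi = min(n, r + half_hi + 1)
        if hits[lo:hi].mean() < 0.5:
            break
        deepest = r
    result = {
        "histograms": {"all": scores, "positive": scores[hits]},
        "window": window,
    }
    if deepest is None:
        result.update(threshold=None, rank=None)
    else:
        result.update(threshold=float(scores[deepest]), rank=deepest + 1)
    return result


def build_signed_network(model: CouplingModel,
                         threshold: float) -> SignedNetwork:
    """Keep the pairs with |J_ij| > threshold as a signed graph."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    g = nx.Graph()
    ids = model.domain_ids
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            j = model.J[a, b]
            if abs(j) > threshold:
                g.add_edge(ids[a], ids[b], weight=float(j),
                           sign=1 if j > 0 else -1)
    return SignedNetwork(g, threshold)


def triangle_census(net: SignedNetwork) -> dict:
    """Classify every triangle by the multiset of its edge signs.

    Returns counts for the classes ``+++``, ``++-``, ``+--`` and ``---``,
    plus the number of negative edges participating in at least one
    triangle.  In this analysis "frustrated" denotes the ``++-`` pattern:
    a single mutual-exclusion link embedded in an otherwise positively
    coupled triple.  (The alternative-pathway signature is ``+--``: two
    exclusions sharing one positive partner.)
    """
    g = net.graph
    counts = {"+++": 0, "++-": 0, "+--": 0, "---": 0}
    negative_in_triangle: set[frozenset] = set()
    adj = {u: set(g.neighbors(u)) for u in g.nodes}
    for u, v in g.edges:
        if u > v:
            u, v = v, u
        for w in adj[u] & adj[v]:
            if w <= v:  # count each triangle once (u < v < w)
                continue
            signs = sorted((g[u][v]["sign"], g[u][w]["sign"],
                            g[v][w]["sign"]), reverse=True)
            key = "".join("+" if s > 0 else "-" for s in signs)
            counts[key] += 1
            for x, y in ((u, v), (u, w), (v, w)):
                if g[x][y]["sign"] < 0:
                    negative_in_triangle.add(frozenset((x, y)))
    counts["negative_edges_in_triangles"] = len(negative_in_triangle)
    return counts


def correlation_vs_distance(net: SignedNetwork, ppm: ProfileMatrix,
                            d_max: int = 5) -> dict:
    """Mean |Pearson r| of profile columns per network distance class.

    Distances are unweighted shortest-path lengths on the coupling network
    (signs and weights ignored); domain pairs in different components — or
    not in the network at all — form the ``baseline`` class.  Directly
    coupled pairs sit at d = 1; if couplings capture direct relations, |r|
    decays with d towards the baseline level.
    """
    missing = set(net.graph.nodes) - set(ppm.domain_ids)
    if missing:
        raise ValueError(f"network nodes missing from PPM: {sorted(missing)}")
    nodes = list(ppm.domain_ids)
    col = {d: i for i, d in enumerate(ppm.domain_ids)}
    x = ppm.entries.astype(np.float64)
    sums: dict[object, list[float]] = {d: [] for d in range(1, d_max + 1)}
    sums["baseline"] = []
    lengths = dict(nx.all_pairs_shortest_path_length(net.graph))
    for a_idx in range(len(nodes)):
        for b_idx in range(a_idx + 1, len(nodes)):
            a, b = nodes[a_idx], nodes[b_idx]
            xa, xb = x[:, col[a]], x[:, col[b]]
            if xa.std() == 0 or xb.std() == 0:
                continue
            r = float(np.corrcoef(xa, xb)[0, 1])
            d = lengths.get(a, {}).get(b)
            if d is None:
                sums["baseline"].append(abs(r))
            elif d <= d_max:
                sums[d].append(abs(r))
    return {k: (float(np.mean(v)) if v else float("nan"), len(v))
            for k, v in sums.items()}
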