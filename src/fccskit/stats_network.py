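"""Cohort statistics and network-level inference.

Association-vs-control testing uses an exact median construction: pooled
scores are dichotomized at the grand median (ties count as "below") and the
resulting 2x2 table is evaluated with the one-sided hypergeometric
(Fisher) tail.  Near/far comparisons use the one-sample Wilcoxon
signed-rank test on per-cell differences (coupled) and the two-sample
rank-sum test (uncoupled).  Network inference enumerates maximal cliques
(candidate ternary complexes) and per-hub maximal independent sets of
neighbors (mutually exclusive partners).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "ScoreCohort",
    "NearFarDataset",
    "EdgeRecord",
    "AssociationNetwork",
    "DynamicsProfile",
    "MedianTestResult",
    "median_association_test",
    "near_far_coupled_test",
    "near_far_uncoupled_test",
    "build_network",
    "find_ternary_complexes",
    "infer_mutual_exclusivity",
    "co_dynamics_distance",
]

LOCATIONS = ("cytosol", "near", "far")


@dataclass
class ScoreCohort:
    """Association scores of one protein pair in one condition."""

    pair: str
    scores: np.ndarray
    cell_line: str = ""
    location: str = "cytosol"
    treatment: str = "none"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        self.scores = self.scores[np.isfinite(self.scores)]
        if self.scores.size < 1:
            raise ValueError("cohort needs at least one finite score")
        if self.location not in LOCATIONS:
            raise ValueError(f"location must be one of {LOCATIONS}, got {self.location!r}")


@dataclass
class NearFarDataset:
    """Cell-wise paired association scores near (< 1.5 um) and far from sites."""

    pair: str
    near: np.ndarray
    far: np.ndarray

    def __post_init__(self) -> None:
        self.near = np.asarray(self.near, float)
        self.far = np.asarray(self.far, float)
        if self.near.shape != self.far.shape:
            raise ValueError("coupled near/far scores must be paired cell-wise (equal lengths)")


@dataclass
class MedianTestResult:
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool = False


def median_association_test(
    pair_scores, neg_scores, alternative: str = "greater"
) -> MedianTestResult:
    """Exact test of median(pair) vs median(control) via the pooled-median split.

    All scores are pooled, each score classified as above the grand median
    or not (ties -> "below"), and the one-sided Fisher exact p-value of the
    2x2 cohort-by-side table is returned.  ``alternative='greater'`` tests
    median(pair) > median(control).
    """
    pair_scores = np.asarray(pair_scores, float)
    neg_scores = np.asarray(neg_scores, float)
    if pair_scores.size == 0 or neg_scores.size == 0:
        raise ValueError("both cohorts must be non-empty")
    pooled = np.concatenate([pair_scores, neg_scores])
    grand = float(np.median(pooled))
    a = int(np.sum(pair_scores > grand))  # pair above
    b = pair_scores.size - a
    c = int(np.sum(neg_scores > grand))  # control above
    d = neg_scores.size - c
    table = ((a, b), (c, d))
    if a + c == 0 or b + d == 0:
        # all scores on one side of (i.e. tied with) the grand median
        return MedianTestResult(1.0, table, degenerate=True)
    _, p = stats.fisher_exact(table, alternative=alternative)
    return MedianTestResult(float(p), table, degenerate=False)


_ALTERNATIVES = ("two-sided", "greater", "less")


def _wilcoxon_all(diff: np.ndarray) -> dict[str, float]:
    n = diff.size
    abs_nonzero = np.abs(diff[diff != 0])
    has_ties = abs_nonzero.size != np.unique(abs_nonzero).size
    has_zeros = bool(np.any(diff == 0))
    exact = n <= 25 and not has_ties and not has_zeros
    out = {}
    for alt in _ALTERNATIVES:
        res = stats.wilcoxon(
            diff,
            zero_method="pratt",
            alternative=alt,
            correction=not exact,
            method="exact" if exact else "approx",
        )
        out[alt] = float(min(res.pvalue, 1.0))
    return out


def near_far_coupled_test(data: NearFarDataset) -> dict[str, float]:
    """One-sample Wilcoxon signed-rank p-values of the cell-wise near-far
    differences, for all three alternatives (two-sided, greater, less).

    Exact null distribution for n <= 25 without ties/zeros; otherwise the
    normal approximation with continuity correction (Pratt zero handling).
    """
    diff = data.near - data.far
    if diff.size < 1:
        raise ValueError("empty dataset")
    if np.all(diff == 0):
        return {"two-sided": 1.0, "greater": 1.0, "less": 1.0, "degenerate": True}
    out = _wilcoxon_all(diff)
    out["degenerate"] = False
    return out


def near_far_uncoupled_test(s1, s2) -> dict[str, float]:
    """Two-sample rank-sum (Mann-Whitney) p-values for all three alternatives.

    Exact for small tie-free samples, tie-corrected normal approximation
    otherwise.  Used when near/far measurements are batched across cells
    rather than paired.
    """
    s1 = np.asarray(s1, float)
    s2 = np.asarray(s2, float)
    if s1.size == 0 or s2.size == 0:
        raise ValueError("both score vectors must be non-empty")
    pooled = np.concatenate([s1, s2])
    has_ties = pooled.size != np.unique(pooled).size
    exact = not has_ties and max(s1.size, s2.size) <= 25
    out = {}
    for alt in _ALTERNATIVES:
        res = stats.mannwhitneyu(
            s1, s2, alternative=alt, method="exact" if exact else "asymptotic"
        )
        out[alt] = float(min(res.pvalue, 1.0))
    return out


@dataclass
class EdgeRecord:
    """Association-test outcome for one protein pair."""

    protein_a: str
    protein_b: str
    p_primary: float
    p_secondary: float | None = None
    ka_median: float = math.nan
    ka_mad: float = math.nan
    score_median: float = math.nan

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.protein_a, self.protein_b)))


@dataclass
class AssociationNetwork:
    """Undirected protein-association network with per-edge statistics."""

    graph: nx.Graph
    p_primary: float = math.nan
    p_secondary: float | None = None

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


def build_network(
    records,
    p_primary: float,
    p_secondary: float | None = None,
    nodes=None,
) -> AssociationNetwork:
    """Keep edges with p < ``p_primary`` (and, when a secondary cell line was
    measured, p < ``p_secondary`` there as well).  Thresholds are strict.
    """
    graph = nx.Graph()
    if nodes is not None:
        graph.add_nodes_from(nodes)
    seen = set()
    for rec in records:
        if rec.protein_a == rec.protein_b:
            raise ValueError(f"self-pair record for {rec.protein_a!r}")
        if rec.key in seen:
            raise ValueError(f"duplicate record for pair {rec.key}")
        seen.add(rec.key)
        graph.add_node(rec.protein_a)
        graph.add_node(rec.protein_b)
        keep = rec.p_primary < p_primary
        if keep and p_secondary is not None and rec.p_secondary is not None:
            keep = rec.p_secondary < p_secondary
        if keep:
            graph.add_edge(
                rec.protein_a,
                rec.protein_b,
                p_primary=rec.p_primary,
                p_secondary=rec.p_secondary,
                ka_median=rec.ka_median,
                ka_mad=rec.ka_mad,
                score_median=rec.score_median,
            )
    return AssociationNetwork(graph, p_primary=p_primary, p_secondary=p_secondary)


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, AssociationNetwork) else net


def find_ternary_complexes(net, min_size: int = 3) -> list[tuple[str, ...]]:
    """Maximal cliques of size >= ``min_size``: candidate fully intra-connected
    complexes.  Deterministically ordered (lexicographic by member names)."""
    graph = _as_graph(net)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph) if len(c) >= min_size]
    return sorted(cliques)


def infer_mutual_exclusivity(net, min_partners: int = 2) -> list[tuple[str, tuple[str, ...]]]:
    """Per-hub maximal sets of pairwise non-associated partners.

    For each node h, every maximal independent set (of size >=
    ``min_partners``) within the subgraph induced on h's neighbors is
    reported as ``(h, partners)``: the partners all bind h but not each
    other, so their associations with h are mutually exclusive.
    """
    graph = _as_graph(net)
    records = []
    for hub in sorted(graph.nodes):
        neighbors = list(graph.neighbors(hub))
        if len(neighbors) < min_partners:
            continue
        complement = nx.complement(graph.subgraph(neighbors))
        for group in nx.find_cliques(complement):
            if len(group) >= min_partners:
                records.append((hub, tuple(sorted(group))))
    return sorted(records)


@dataclass
class DynamicsProfile:
    """Per-protein median exchange/diffusion kinetics.

    ``medians`` maps protein -> dict with (a subset of) keys ``tau_half``,
    ``mobile_fraction``, ``tau_d`` and their ``*_mad`` companions.
    """

    medians: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def proteins(self) -> list[str]:
        return sorted(self.medians)


def co_dynamics_distance(profile: DynamicsProfile) -> tuple[list[str], np.ndarray]:
    """Pairwise Euclidean distances in z-scored (tau_half, mobile fraction) space.

    Coordinates are standardized across proteins to zero mean and unit
    sample variance (ddof=1).  Returns (protein labels, distance matrix).
    """
    proteins = [
        p
        for p in profile.proteins
        if "tau_half" in profile.medians[p] and "mobile_fraction" in profile.medians[p]
    ]
    if len(proteins) < 3:
        raise ValueError("need at least 3 proteins with both medians")
    coords = np.array(
        [
            [profile.medians[p]["tau_half"], profile.medians[p]["mobile_fraction"]]
            for p in proteins
        ]
    )
    sd = coords.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero variance in a coordinate: z-scores undefined")
    z = (coords - coords.mean(axis=0)) / sd
    diff = z[:, None, :] - z[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    return proteins, dist
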