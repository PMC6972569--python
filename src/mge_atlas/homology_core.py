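"""Protein homology: local alignment, score-ratio reciprocal best hits,
pivot core-genome analysis, conservation networks, single-transitive-link
family clustering and random-walk community detection.

The orthology criterion is the normalized bidirectional best hit: raw local
alignment scores (Smith-Waterman, BLOSUM62, gap open 11 / extend 1) are
normalized by the query's self-alignment score, two proteins are orthologs
when each is the other's best hit and both directed normalized scores exceed
a threshold (default 30%).  Families are single-transitive-link clusters with
identity and coverage constraints; communities in the conservation network
are found by agglomerating short random walks (walktrap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import igraph
import networkx as nx
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "HomologyHit",
    "OrthologMap",
    "GeneFamily",
    "align_local",
    "self_score",
    "raw_score",
    "normalized_bdbh",
    "pivot_core_analysis",
    "conservation_network",
    "cluster_families",
    "detect_communities",
]

GAP_OPEN = 11
GAP_EXTEND = 1
DEFAULT_BDBH_THRESHOLD = 30.0


def _make_aligner(mode: str) -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = mode
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -GAP_OPEN
    a.extend_gap_score = -GAP_EXTEND
    return a


_LOCAL = _make_aligner("local")


@dataclass(frozen=True)
class HomologyHit:
    """A directed pairwise protein comparison."""

    query_id: str
    subject_id: str
    raw_score: float
    pct_identity: float
    query_coverage: float
    subject_coverage: float
    normalized_score: float


@dataclass
class OrthologMap:
    """BDBH ortholog pairs between two elements' proteomes."""

    element_a: str
    element_b: str
    pairs: list[tuple[str, str]]
    threshold_pct: float

    def swapped(self) -> "OrthologMap":
        return OrthologMap(
            self.element_b,
            self.element_a,
            [(b, a) for a, b in self.pairs],
            self.threshold_pct,
        )


@dataclass
class GeneFamily:
    family_id: str
    members: list[str]
    is_core: bool = False


@lru_cache(maxsize=400_000)
def raw_score(a: str, b: str) -> float:
    """Optimal local alignment score only (no traceback); cached."""
    if not a or not b:
        raise ValueError("empty protein sequence")
    s = _LOCAL.score(a, b)
    return float(max(s, 0.0))


def self_score(a: str) -> float:
    return raw_score(a, a)


def align_local(a: str, b: str, query_id: str = "query",
                subject_id: str = "subject") -> HomologyHit:
    """Optimal local alignment of two proteins with identity and coverage.

    The normalized score is 100 x score(a, b) / score(a, a) (directional,
    query-side).  A pair with no positive-scoring cell yields a zero hit.
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    score = raw_score(a, b)
    if score <= 0:
        return HomologyHit(query_id, subject_id, 0.0, 0.0, 0.0, 0.0, 0.0)
    aln = _LOCAL.align(a, b)[0]  # leftmost optimal traceback: deterministic
    ident = aligned_cols = 0
    q_span = s_span = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        q_span += qe - qs
        s_span += se - ss
        for i in range(qe - qs):
            aligned_cols += 1
            if a[qs + i] == b[ss + i]:
                ident += 1
    pct_identity = 100.0 * ident / aligned_cols if aligned_cols else 0.0
    return HomologyHit(
        query_id,
        subject_id,
        score,
        pct_identity,
        100.0 * q_span / len(a),
        100.0 * s_span / len(b),
        100.0 * score / self_score(a),
    )


def _best_hit(query: str, proteome: dict[str, str]) -> tuple[str | None, float]:
    """Best subject for ``query`` by raw score; ties broken by higher
    identity, then lexicographic subject id."""
    best_ids: list[str] = []
    best = 0.0
    for sid, sseq in proteome.items():
        s = raw_score(query, sseq)
        if s > best:
            best, best_ids = s, [sid]
        elif s == best and s > 0:
            best_ids.append(sid)
    if not best_ids:
        return None, 0.0
    if len(best_ids) > 1:
        best_ids.sort(
            key=lambda sid: (-align_local(query, proteome[sid]).pct_identity, sid)
        )
    return best_ids[0], best


def normalized_bdbh(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    threshold_pct: float = DEFAULT_BDBH_THRESHOLD,
    element_a: str = "A",
    element_b: str = "B",
    mode: str = "both",
) -> OrthologMap:
    """Self-score-normalized bidirectional best hits between two proteomes.

    ``mode="both"`` requires both directed normalized scores above the
    threshold (equivalently min > t); ``mode="either"`` requires one.
    """
    if not (0 < threshold_pct <= 100):
        raise ValueError("threshold_pct must be in (0, 100]")
    if not proteome_a or not proteome_b:
        raise ValueError("empty proteome")
    if mode not in {"both", "either"}:
        raise ValueError(f"unknown mode {mode!r}")
    best_ab = {q: _best_hit(qseq, proteome_b) for q, qseq in proteome_a.items()}
    best_ba = {q: _best_hit(qseq, proteome_a) for q, qseq in proteome_b.items()}
    pairs = []
    for p, (q, s_ab) in best_ab.items():
        if q is None:
            continue
        back, s_ba = best_ba[q]
        if back != p:
            continue
        norm_ab = 100.0 * s_ab / self_score(proteome_a[p])
        norm_ba = 100.0 * s_ba / self_score(proteome_b[q])
        ok = (
            norm_ab > threshold_pct and norm_ba > threshold_pct
            if mode == "both"
            else norm_ab > threshold_pct or norm_ba > threshold_pct
        )
        if ok:
            pairs.append((p, q))
    pairs.sort()
    return OrthologMap(element_a, element_b, pairs, threshold_pct)


def pivot_core_analysis(
    proteomes: dict[str, dict[str, str]],
    pivot_id: str,
    presence_fraction: float = 0.8,
    threshold_pct: float = DEFAULT_BDBH_THRESHOLD,
) -> tuple[list[str], int]:
    """Count, for each pivot protein, how many elements carry a BDBH ortholog.

    Returns the pivot proteins present in at least ``presence_fraction`` of
    all elements (the pivot itself counts as possessing its own proteins)
    and the core size.
    """
    if pivot_id not in proteomes:
        raise KeyError(f"unknown pivot {pivot_id!r}")
    pivot = proteomes[pivot_id]
    n_elements = len(proteomes)
    presence = {p: 1 for p in pivot}  # pivot possesses its own proteins
    for other_id, other in proteomes.items():
        if other_id == pivot_id:
            continue
        om = normalized_bdbh(pivot, other, threshold_pct, pivot_id, other_id)
        for p, _q in om.pairs:
            presence[p] += 1
    core = sorted(
        p for p, k in presence.items() if k / n_elements >= presence_fraction
    )
    return core, len(core)


def conservation_network(
    proteomes: dict[str, dict[str, str]],
    threshold_pct: float = DEFAULT_BDBH_THRESHOLD,
) -> nx.Graph:
    """Element graph weighted by the number of BDBH ortholog pairs."""
    if len(proteomes) < 2:
        raise ValueError("need at least 2 elements")
    g = nx.Graph()
    g.add_nodes_from(proteomes)
    ids = sorted(proteomes)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            w = len(normalized_bdbh(proteomes[a], proteomes[b],
                                    threshold_pct, a, b).pairs)
            if w > 0:
                g.add_edge(a, b, weight=w)
    return g


def cluster_families(
    proteins: dict[str, str],
    min_identity_pct: float = 25.0,
    min_coverage_pct: float = 60.0,
) -> list[GeneFamily]:
    """Single-transitive-link families under identity + query-coverage cuts.

    Two proteins are linked when their local alignment reaches the
    identity threshold and covers at least ``min_coverage_pct`` of BOTH
    sequences; families are the connected components, singletons included.
    Requiring coverage on both sides stands in for the significance filter
    of a database search: short high-identity local alignments between
    unrelated proteins otherwise chain everything together.
    """
    if not (0 < min_identity_pct <= 100 and 0 < min_coverage_pct <= 100):
        raise ValueError("thresholds must be in (0, 100]")
    g = nx.Graph()
    g.add_nodes_from(proteins)
    ids = sorted(proteins)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            hit = align_local(proteins[a], proteins[b], a, b)
            if (
                hit.pct_identity >= min_identity_pct
                and min(hit.query_coverage, hit.subject_coverage) >= min_coverage_pct
            ):
                g.add_edge(a, b)
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0]
    )
    return [
        GeneFamily(family_id=f"Fam_{i:04d}", members=c) for i, c in enumerate(comps)
    ]


def detect_communities(graph: nx.Graph, walk_length: int = 4) -> list[set[str]]:
    """Walktrap community detection on a weighted element graph.

    Short random walks tend to stay within densely connected groups; the
    agglomerative merge sequence is cut at maximum modularity.  Disconnected
    components are never merged.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges]
    weights = [graph[u][v].get("weight", 1.0) for u, v in graph.edges]
    ig = igraph.Graph(n=len(nodes), edges=edges)
    dendro = ig.community_walktrap(
        weights=weights if edges else None, steps=walk_length
    )
    clustering = dendro.as_clustering()
    return [set(nodes[i] for i in comm) for comm in clustering]
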