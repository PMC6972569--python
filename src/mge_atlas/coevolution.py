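"""Distance-based phylogenetics over core-protein sets.

The family's central evolutionary claim is topological: elements hosted by
the two archaeal orders form two monophyletic groups congruent with their
host phylogeny.  That property is tested here with desk-scale distance
methods: Poisson-corrected pairwise protein distances, concatenation as a
length-weighted mean of per-family distances, neighbor joining with a
deterministic tie-break, monophyly testing by bipartition, and
Robinson-Foulds distances to quantify tree congruence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import dendropy
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .homology_core import GAP_EXTEND, GAP_OPEN

__all__ = [
    "DistanceMatrix",
    "pairwise_distance",
    "p_distance",
    "poisson_correct",
    "concatenated_distances",
    "nj_tree",
    "test_monophyly",
    "rf_distance",
    "SATURATION_P",
]

SATURATION_P = 0.95
_SATURATED_D = -math.log(1.0 - SATURATION_P)


def _make_global() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -GAP_OPEN
    a.extend_gap_score = -GAP_EXTEND
    return a


_GLOBAL = _make_global()


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        if not np.isfinite(m).all() or (m < 0).any():
            raise ValueError("entries must be finite and non-negative")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])


@lru_cache(maxsize=200_000)
def p_distance(a: str, b: str) -> float:
    """Proportion of differing residues over aligned non-gap columns of the
    optimal global alignment."""
    if not a or not b:
        raise ValueError("empty protein sequence")
    if a == b:
        return 0.0
    aln = _GLOBAL.align(a, b)[0]
    ident = cols = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        for i in range(qe - qs):
            cols += 1
            if a[qs + i] == b[ss + i]:
                ident += 1
    if cols == 0:
        return 1.0
    return 1.0 - ident / cols


def poisson_correct(p: float) -> tuple[float, bool]:
    """Poisson-corrected distance d = -ln(1-p); saturated at p >= 0.95."""
    if p >= SATURATION_P:
        return _SATURATED_D, True
    return -math.log(1.0 - p), False


def pairwise_distance(a: str, b: str) -> float:
    """Poisson-corrected protein distance (saturation capped)."""
    d, _saturated = poisson_correct(p_distance(a, b))
    return d


def concatenated_distances(
    element_families: dict[str, dict[str, str]],
) -> DistanceMatrix:
    """Concatenated core distance: length-weighted mean over shared families.

    ``element_families`` maps element id -> {family id -> protein sequence}.
    The per-pair distance averages the per-family Poisson distances weighted
    by mean family sequence length over the families present in both
    elements; a pair sharing no family is an error (the elements cannot be
    placed on one tree).
    """
    taxa = sorted(element_families)
    if any(not fams for fams in element_families.values()):
        empty = [e for e, f in element_families.items() if not f]
        raise ValueError(f"elements without core families: {empty}")
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            fa, fb = element_families[taxa[i]], element_families[taxa[j]]
            shared = sorted(set(fa) & set(fb))
            if not shared:
                raise ValueError(
                    f"elements {taxa[i]!r} and {taxa[j]!r} share no core family"
                )
            weights = dists = 0.0
            for fam in shared:
                w = (len(fa[fam]) + len(fb[fam])) / 2.0
                dists += w * pairwise_distance(fa[fam], fb[fam])
                weights += w
            m[i, j] = m[j, i] = dists / weights
    return DistanceMatrix(taxa, m)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining with a deterministic lowest-index-pair tie-break.

    Recovers additive matrices exactly.  Negative branch lengths arising
    from noise are clamped to zero.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    active = list(range(n))
    d = {(i, j): dm.matrix[i, j] for i in range(n) for j in range(n)}
    newick = {i: t for i, t in enumerate(dm.taxa)}
    next_id = n
    while len(active) > 2:
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (len(active) - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _q, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (len(active) - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        newick[next_id] = f"({newick[i]}:{li:.10f},{newick[j]}:{lj:.10f})"
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[next_id, k] = d[k, next_id] = max(dk, 0.0)
        d[next_id, next_id] = 0.0
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    i, j = active
    l = max(d[i, j], 0.0)
    text = f"({newick[i]}:{l / 2:.10f},{newick[j]}:{l / 2:.10f});"
    tree = dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def test_monophyly(tree: dendropy.Tree, leaf_subset: set[str]) -> bool:
    """True iff some edge bipartitions the leaves exactly into subset vs
    complement (unrooted convention)."""
    labels = _leaf_labels(tree)
    subset = set(leaf_subset)
    unknown = subset - labels
    if unknown:
        raise ValueError(f"unknown leaves: {sorted(unknown)}")
    if not subset or subset == labels:
        return True
    complement = labels - subset
    for node in tree.preorder_node_iter():
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == subset or below == complement:
            return True
    return False


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: non-trivial bipartitions in exactly one tree."""
    if _leaf_labels(t1) != _leaf_labels(t2):
        raise ValueError("trees have different leaf sets")
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick", unquoted_underscores=True),
        schema="newick", taxon_namespace=tns, preserve_underscores=True,
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick", unquoted_underscores=True),
        schema="newick", taxon_namespace=tns, preserve_underscores=True,
    )
    a.is_rooted = False
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))
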