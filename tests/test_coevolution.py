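"""Distance computation, neighbor joining, monophyly and tree congruence."""

import math

import dendropy
import numpy as np
import pytest

from mge_atlas.coevolution import (
    DistanceMatrix,
    concatenated_distances,
    nj_tree,
    p_distance,
    pairwise_distance,
    poisson_correct,
    rf_distance,
)
from mge_atlas.coevolution import test_monophyly as is_monophyletic

AA = "ACDEFGHIKLMNPQRSTVWY"


def mutate_fraction(seq, k, rng):
    """Exactly k substitutions at distinct random sites."""
    out = list(seq)
    for i in rng.choice(len(seq), size=k, replace=False):
        out[i] = AA[(AA.index(out[i]) + 1) % 20]
    return "".join(out)


class TestDistances:
    def test_identical_proteins_distance_zero(self):
        assert pairwise_distance("MKLVV" * 20, "MKLVV" * 20) == 0.0

    def test_poisson_closed_form_at_ten_percent(self, rng):
        seq = "".join(AA[i] for i in rng.integers(0, 20, 200))
        other = mutate_fraction(seq, 20, rng)
        assert p_distance(seq, other) == pytest.approx(0.1)
        assert pairwise_distance(seq, other) == pytest.approx(
            -math.log(0.9), abs=1e-9
        )
        assert pairwise_distance(seq, other) == pytest.approx(0.10536, abs=1e-4)

    def test_saturation_cap(self):
        d, saturated = poisson_correct(0.97)
        assert saturated and d == pytest.approx(-math.log(0.05))

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            pairwise_distance("", "MK")


class TestConcatenated:
    def test_identical_families_zero(self, rng):
        fams = {f"f{i}": "".join(AA[j] for j in rng.integers(0, 20, 80))
                for i in range(7)}
        dm = concatenated_distances({"a": dict(fams), "b": dict(fams),
                                     "c": dict(fams)})
        assert np.allclose(dm.matrix, 0)

    def test_length_weighted_mean(self, rng):
        f1 = "".join(AA[i] for i in rng.integers(0, 20, 100))
        f2 = "".join(AA[i] for i in rng.integers(0, 20, 300))
        a = {"f1": f1, "f2": f2}
        b = {"f1": mutate_fraction(f1, 20, rng),  # p=0.2
             "f2": mutate_fraction(f2, 30, rng)}  # p=0.1
        dm = concatenated_distances({"a": a, "b": b})
        d1 = -math.log(0.8)
        d2 = -math.log(0.9)
        expected = (100 * d1 + 300 * d2) / 400
        assert dm.get("a", "b") == pytest.approx(expected, rel=1e-6)

    def test_partial_overlap_uses_shared_subset(self, dataset, rng):
        t = dataset.truth["elements"]
        remnant = next(e for e, v in t.items() if v["state"] == "remnant")
        full = next(e for e, v in t.items()
                    if v["order"] == "A" and v["state"] == "integrated")
        fams_r = {k: v for k, v in t[remnant]["families"].items()}
        fams_f = {k: v for k, v in t[full]["families"].items()
                  if k.startswith("t26-")}
        shared = sorted(set(fams_r) & set(fams_f))
        assert 0 < len(shared) < len(fams_f)
        dm = concatenated_distances({"r": fams_r, "f": fams_f})
        # direct computation on the shared subset
        num = den = 0.0
        for k in shared:
            w = (len(fams_r[k]) + len(fams_f[k])) / 2
            num += w * pairwise_distance(fams_r[k], fams_f[k])
            den += w
        assert dm.get("r", "f") == pytest.approx(num / den)

    def test_disjoint_families_error(self, rng):
        a = {"f1": "MKLW" * 20}
        b = {"f2": "MKLW" * 20}
        with pytest.raises(ValueError, match="share no core family"):
            concatenated_distances({"a": a, "b": b})


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0.0]]))
        tree = nj_tree(dm)
        # three-point formulas give leaf branches 2, 3 and 7; on the
        # unrooted tree this is equivalent to exact patristic recovery
        pdm = tree.phylogenetic_distance_matrix()
        get = tree.taxon_namespace.get_taxon
        assert pdm.distance(get("A"), get("B")) == pytest.approx(5)
        assert pdm.distance(get("A"), get("C")) == pytest.approx(9)
        assert pdm.distance(get("B"), get("C")) == pytest.approx(10)
        lens = {lf.taxon.label: lf.edge.length
                for lf in tree.leaf_node_iter()}
        assert lens["A"] == pytest.approx(2)
        assert lens["B"] == pytest.approx(3)

    def test_additive_four_taxon_matrix_recovered(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) -> additive distances
        d = {("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 8,
             ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 9}
        taxa = ["A", "B", "C", "D"]
        m = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = taxa.index(x), taxa.index(y)
            m[i, j] = m[j, i] = v
        tree = nj_tree(DistanceMatrix(taxa, m))
        ref = dendropy.Tree.get(data="((A:2,B:3):1,(C:4,D:5):0);",
                                schema="newick")
        assert rf_distance(tree, ref) == 0
        # branch lengths recovered exactly: patristic distances match input
        pdm = tree.phylogenetic_distance_matrix()
        for (x, y), v in d.items():
            tx = tree.taxon_namespace.get_taxon(x)
            ty = tree.taxon_namespace.get_taxon(y)
            assert pdm.distance(tx, ty) == pytest.approx(v)

    def test_equidistant_taxa_deterministic(self):
        m = np.ones((4, 4)) - np.eye(4)
        taxa = ["A", "B", "C", "D"]
        t1 = nj_tree(DistanceMatrix(taxa, m.copy()))
        t2 = nj_tree(DistanceMatrix(taxa, m.copy()))
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_matches_dendropy_nj_topology_on_random_matrices(self, rng):
        for _ in range(5):
            k = 8
            taxa = [f"T{i}" for i in range(k)]
            m = rng.random((k, k)) + 0.2
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            mine = nj_tree(DistanceMatrix(taxa, m))
            csv = "," + ",".join(taxa) + "\n" + "\n".join(
                taxa[i] + "," + ",".join(str(m[i, j]) for j in range(k))
                for i in range(k)
            )
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=__import__("io").StringIO(csv), delimiter=","
            )
            ref = pdm.nj_tree()
            assert rf_distance(mine, ref) == 0

    def test_too_few_taxa_errors(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))


class TestMonophyly:
    def test_clade_and_non_clade(self):
        t = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);",
                              schema="newick")
        assert is_monophyletic(t, {"A", "B"})
        assert not is_monophyletic(t, {"A", "C"})

    def test_complement_convention(self):
        t = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);",
                              schema="newick")
        assert is_monophyletic(t, {"C", "D"})
        assert is_monophyletic(t, {"A", "B", "C", "D"})

    def test_unknown_leaf_errors(self):
        t = dendropy.Tree.get(data="((A:1,B:1):1,C:1);", schema="newick")
        with pytest.raises(ValueError):
            is_monophyletic(t, {"Z"})

    def test_agrees_with_bipartition_enumeration(self, rng):
        import random as _random

        import dendropy.simulate

        for i in range(3):
            tns = dendropy.TaxonNamespace([f"T{k}" for k in range(12)])
            t = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
                num_extant_tips=12, rng=_random.Random(i),
            )
            t.encode_bipartitions()
            all_splits = set()
            for edge in t.preorder_edge_iter():
                if edge.head_node is t.seed_node:
                    continue
                below = frozenset(
                    lf.taxon.label for lf in edge.head_node.leaf_iter()
                )
                all_splits.add(below)
                all_splits.add(frozenset(
                    {f"T{k}" for k in range(12)} - below
                ))
            for _ in range(20):
                size = int(rng.integers(1, 12))
                sub = set(rng.choice([f"T{k}" for k in range(12)],
                                     size=size, replace=False))
                assert is_monophyletic(t, sub) == (frozenset(sub) in all_splits)


class TestRfDistance:
    def test_identical_trees_zero(self):
        t1 = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);",
                               schema="newick")
        t2 = dendropy.Tree.get(data="((C:2,D:2):1,(A:2,B:2):1);",
                               schema="newick")
        assert rf_distance(t1, t2) == 0

    def test_distinct_four_leaf_topologies(self):
        t1 = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);",
                               schema="newick")
        t2 = dendropy.Tree.get(data="((A:1,C:1):1,(B:1,D:1):1);",
                               schema="newick")
        assert rf_distance(t1, t2) == 2

    def test_single_nni_on_six_leaves(self):
        t1 = dendropy.Tree.get(
            data="(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);",
            schema="newick")
        t2 = dendropy.Tree.get(
            data="(((A:1,(C:1,D:1):1):1,B:1):1,(E:1,F:1):1);",
            schema="newick")
        assert rf_distance(t1, t2) == 2

    def test_leaf_set_mismatch_errors(self):
        t1 = dendropy.Tree.get(data="((A:1,B:1):1,C:1);", schema="newick")
        t2 = dendropy.Tree.get(data="((A:1,B:1):1,D:1);", schema="newick")
        with pytest.raises(ValueError):
            rf_distance(t1, t2)


class TestCoevolutionInvariants:
    @staticmethod
    def _element_tree(ds, host_only=False):
        fams = {}
        for eid, t in ds.truth["elements"].items():
            if host_only and t["host"] is None:
                continue
            fams[eid if not host_only else t["host"]] = {
                k: v for k, v in t["families"].items() if k.startswith("t26-")
            }
        return nj_tree(concatenated_distances(fams))

    def test_two_clade_recovery_over_20_seeds(self, monophyly_stats):
        """Order A and order B elements each form a clade on the
        concatenated core NJ tree in >=95% of seeds."""
        assert monophyly_stats >= 0.95

    def test_rf_zero_without_transfer_and_monotone_with_rate(self):
        """Element tree equals the host-marker tree at zero transfer rate;
        the median RF distance is non-decreasing in the transfer rate."""
        from mge_atlas.synthetic_data import GeneratorConfig, generate_dataset

        medians = []
        for rate in (0.0, 0.4, 0.8):
            rfs = []
            for seed in range(20):
                ds = generate_dataset(
                    GeneratorConfig(seed=300 + seed, transfer_rate=rate)
                )
                etree = self._element_tree(ds, host_only=True)
                markers = {
                    h: dict(ms) for h, ms in ds.host_markers.items()
                }
                htree = nj_tree(concatenated_distances(markers))
                rfs.append(rf_distance(etree, htree))
            medians.append(float(np.median(rfs)))
        assert medians[0] == 0.0
        assert medians == sorted(medians)
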