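"""Att-site direct repeats, element limits, split-integrase reconstruction,
integration typing, att/tRNA relations and att-exchange inversions."""

import numpy as np
import pytest

from mge_atlas.genecalling import find_orfs, revcomp
from mge_atlas.integration import (
    AttSite,
    att_sequences_match,
    att_trna_report,
    call_element_limits,
    classify_integration_type,
    detect_att_exchange,
    find_direct_repeats,
    reconstruct_split_integrase,
)
from mge_atlas.sequence_io import Feature, GenomeRecord
from mge_atlas.synthetic_data import ElementDesign, implant_element


def rand_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def brute_force_repeats(seq, min_len, max_mm):
    """O(n^2) oracle: for every offset, find runs of near-identity with the
    middle-zone rule, vectorised over positions."""
    arr = np.frombuffer(seq.encode(), np.uint8)
    n = len(arr)
    found = []
    for d in range(min_len, n):
        eq = arr[: n - d] == arr[d:]
        # scan maximal windows of length >= min_len satisfying the rule
        i = 0
        while i + min_len <= n - d:
            L = min_len
            best = None
            while i + L <= n - d and L <= 250:
                window = eq[i : i + L]
                third = L // 3
                mm = np.nonzero(~window)[0]
                if (
                    len(mm) <= max_mm
                    and all(third <= x < L - third for x in mm)
                    and d >= L
                ):
                    best = (i, i + d, L)
                L += 1
            if best:
                found.append(best)
                i += best[2]
            else:
                i += 1
    return found


class TestDirectRepeats:
    def test_implanted_pair_with_central_mismatches_recovered(self, rng):
        seq = list(rand_dna(rng, 5000))
        unit = rand_dna(rng, 50)
        mutated = list(unit)
        mutated[23] = "A" if unit[23] != "A" else "C"
        mutated[26] = "G" if unit[26] != "G" else "T"
        seq[1000:1050] = unit
        seq[3000:3050] = "".join(mutated)
        seq = "".join(seq)
        pairs = find_direct_repeats(seq, min_len=40, max_mid_mismatches=3)
        assert pairs, "implanted repeat not found"
        top = pairs[0]
        assert top.start1 <= 1000 < 1050 <= top.start1 + top.length + 10
        assert 2990 <= top.start2 <= 3000
        assert len(top.mismatch_positions) <= 3

    def test_agrees_with_brute_force_oracle(self, rng):
        seq = list(rand_dna(rng, 800))
        unit = rand_dna(rng, 44)
        seq[100:144] = unit
        m = list(unit)
        m[20] = {"A": "C"}.get(m[20], "A")
        seq[500:544] = "".join(m)
        seq = "".join(seq)
        mine = find_direct_repeats(seq, min_len=40, max_mid_mismatches=3)
        oracle = brute_force_repeats(seq, 40, 3)
        # the oracle enumerates every valid window; the implementation must
        # find a pair covering the implanted site whenever the oracle does
        assert bool(mine) == bool(oracle)
        if mine:
            spans = [(p[0], p[1]) for p in oracle]
            assert any(
                abs(mine[0].start1 - a) <= 5 and abs(mine[0].start2 - b) <= 5
                for a, b in spans
            )

    def test_no_repeats_in_plain_random_sequence(self, rng):
        assert find_direct_repeats(rand_dna(rng, 3000), 40, 3) == []

    def test_mismatch_in_first_third_rejected(self, rng):
        seq = list(rand_dna(rng, 2000))
        unit = rand_dna(rng, 45)
        m = list(unit)
        m[2] = {"A": "C"}.get(m[2], "A")  # mismatch at position 2: edge zone
        seq[300:345] = unit
        seq[1300:1345] = "".join(m)
        seq = "".join(seq)
        pairs = find_direct_repeats(seq, min_len=45, max_mid_mismatches=3)
        # only acceptable as a shorter repeat that drops the bad edge
        for p in pairs:
            third = p.length // 3
            assert all(third <= x < p.length - third
                       for x in p.mismatch_positions)

    def test_min_len_validation(self):
        with pytest.raises(ValueError):
            find_direct_repeats("ACGT" * 100, min_len=10)


class TestAttMatch:
    def test_exact_and_middle_mismatch(self):
        a = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
        b = list(a)
        b[20] = "T"
        assert att_sequences_match(a, a)
        assert att_sequences_match(a, "".join(b))
        b = list(a)
        b[1] = "T"  # first third: not tolerated
        assert not att_sequences_match(a, "".join(b))


@pytest.fixture(scope="module")
def detected_elements(dataset):
    """Truth-guided AttSite/Element objects for the default dataset."""
    from mge_atlas.integration import Element

    out = {}
    for eid, t in dataset.truth["elements"].items():
        if t["host"] is None or t["state"] == "remnant":
            continue
        host = next(h for h in dataset.hosts if h.id == t["host"])
        (l0, l1), (r0, r1) = t["att"]["left"], t["att"]["right"]
        out[eid] = (
            host,
            Element(
                id=eid, genome_id=host.id, start=l0, end=r1,
                att_left=AttSite(host.sequence[l0:l1], l0, l1, "attL"),
                att_right=AttSite(host.sequence[r0:r1], r0, r1, "attR"),
            ),
            t,
        )
    return out


class TestElementLimits:
    @staticmethod
    def _intact_element(dataset):
        eid, t = next(
            (e, t) for e, t in sorted(dataset.truth["elements"].items())
            if t["state"] == "integrated"
        )
        host = next(h for h in dataset.hosts if h.id == t["host"])
        return host, t

    def test_truth_span_recovered(self, dataset):
        host, t = self._intact_element(dataset)
        anchors = [
            Feature(f"a{i}", "CDS", s, e)
            for i, (name, (s, e)) in enumerate(sorted(t["genes"].items()))
            if name.startswith("t26-")
        ]
        el = call_element_limits(host, anchors)
        assert el is not None and el.span == tuple(t["span"])
        assert len(el.att_left) == len(t["att"]["sequence"])

    def test_deleted_attr_gives_not_found(self, dataset, rng):
        host, t = self._intact_element(dataset)
        r0, r1 = t["att"]["right"]
        seq = host.sequence[:r0] + rand_dna(rng, r1 - r0) + host.sequence[r1:]
        broken = GenomeRecord(host.id, seq, features=host.features)
        anchors = [
            Feature(f"a{i}", "CDS", s, e)
            for i, (name, (s, e)) in enumerate(sorted(t["genes"].items()))
            if name.startswith("t26-")
        ]
        assert call_element_limits(broken, anchors) is None

    def test_two_elements_in_one_genome(self, dataset, rng):
        # implant a second element into a host that already carries one
        host = next(h for h in dataset.hosts if h.id == "hostA2")
        t1 = dataset.truth["elements"]["hostA2_IP1"]
        donor = dataset.truth["elements"]["hostA3_IP1"]
        design = ElementDesign(
            id="extra", order="A", integration_type="II", state="integrated",
            genes={k: v for k, v in donor["families"].items()
                   if k.startswith("t26-")},
            integrase_protein=dataset.truth["elements"]["hostA3_IP1"][
                "integrase_protein"],
            rep_class=None, target_trna="Lys", att_length=60, ori_signal=False,
        )
        g2, t2 = implant_element(host, design, "Lys",
                                 np.random.default_rng(5))
        assert len(g2.sequence) == len(host.sequence) + t2["circle_length"]
        shift = t2["circle_length"] if t2["span"][0] < t1["span"][0] else 0
        first = [t1["span"][0] + shift, t1["span"][1] + shift]
        spans = sorted([t2["span"], first])
        assert spans[0][1] <= spans[1][0]  # non-overlapping

    def test_no_anchors_errors(self, dataset):
        host = dataset.hosts[0]
        with pytest.raises(ValueError):
            call_element_limits(host, [])


class TestReconstruction:
    def test_type_one_round_trip(self, detected_elements):
        checked = 0
        for eid, (host, el, t) in detected_elements.items():
            if t["integrase_type"] != "I":
                continue
            rec = reconstruct_split_integrase(
                host, el.att_left, el.att_right,
                [(el.att_left.start, el.att_left.end)],
            )
            assert rec.protein == t["integrase_protein"]
            checked += 1
        assert checked >= 3

    def test_intact_type_two_returned_unchanged(self, detected_elements):
        for eid, (host, el, t) in detected_elements.items():
            if t["integrase_type"] != "II":
                continue
            gs, ge = t["genes"]["int"]
            rec = reconstruct_split_integrase(
                host, el.att_left, el.att_right, [(gs, ge)]
            )
            assert rec.protein == t["integrase_protein"]
            break

    def test_incompatible_frames_error(self, rng):
        # atts placed in random DNA: no join can translate cleanly
        seq = rand_dna(rng, 4000)
        g = GenomeRecord("g", seq)
        attl = AttSite(seq[1000:1050], 1000, 1050, "attL")
        attr = AttSite(seq[3000:3050], 3000, 3050, "attR")
        with pytest.raises(ValueError, match="open reading frames"):
            reconstruct_split_integrase(g, attl, attr, [(900, 1100)])


class TestClassification:
    def test_type_one_from_fragments(self, detected_elements):
        for eid, (host, el, t) in detected_elements.items():
            el.genes = [
                Feature("c", "CDS", el.att_left.start, el.att_left.start + 400,
                        attributes={"product": "integrase", "fragment": "C"}),
                Feature("n", "CDS", el.att_right.start - 360,
                        el.att_right.start,
                        attributes={"product": "integrase", "fragment": "N"}),
            ]
            assert classify_integration_type(el) == "I"
            break

    def test_type_two_from_intact_gene(self, detected_elements):
        for eid, (host, el, t) in detected_elements.items():
            if t["integrase_type"] != "II":
                continue
            gs, ge = t["genes"]["int"]
            el.genes = [
                Feature("i", "CDS", gs, ge, attributes={"product": "integrase"})
            ]
            assert classify_integration_type(el) == "II"
            break

    def test_none_without_integrase(self, detected_elements):
        eid, (host, el, t) = next(iter(detected_elements.items()))
        el.genes = [Feature("x", "CDS", el.start + 100, el.start + 400,
                            attributes={"product": "hypothetical protein"})]
        assert classify_integration_type(el) is None

    def test_invariant_under_genome_reverse_complement(self, detected_elements):
        # mirror the element and its features; the call must not change
        for eid, (host, el, t) in detected_elements.items():
            n = len(host.sequence)
            el.genes = [
                Feature("c", "CDS", el.att_left.start, el.att_left.start + 300,
                        attributes={"product": "integrase", "fragment": "C"}),
            ]
            fwd = classify_integration_type(el)
            from mge_atlas.integration import Element

            mirrored = Element(
                id=el.id, genome_id=el.genome_id,
                start=n - el.end, end=n - el.start,
                att_left=AttSite(revcomp(el.att_right.sequence),
                                 n - el.att_right.end, n - el.att_right.start,
                                 "attL"),
                att_right=AttSite(revcomp(el.att_left.sequence),
                                  n - el.att_left.end, n - el.att_left.start,
                                  "attR"),
                genes=[
                    Feature("c", "CDS", n - (el.att_left.start + 300),
                            n - el.att_left.start, "-",
                            {"product": "integrase", "fragment": "C"})
                ],
            )
            assert classify_integration_type(mirrored) == fwd
            break


class TestAttTrnaReport:
    def test_target_isotypes_reported(self, dataset, detected_elements):
        hits = 0
        for eid, (host, el, t) in detected_elements.items():
            trnas = [f for f in host.features if f.kind == "tRNA"]
            rep = att_trna_report(el, trnas)
            assert rep["target_trna"] == t["target_trna"]
            assert rep["overlap_length"] > 0
            assert rep["t_stem_palindrome"] is True
            hits += 1
        assert hits >= 8

    def test_intergenic_att_reports_none(self, rng):
        from mge_atlas.integration import Element

        seq = rand_dna(rng, 2000)
        el = Element(
            id="e", genome_id="g", start=500, end=1500,
            att_left=AttSite(seq[500:550], 500, 550, "attL"),
            att_right=AttSite(seq[1450:1500], 1450, 1500, "attR"),
        )
        rep = att_trna_report(el, [])
        assert rep["target_trna"] is None and rep["overlap_length"] == 0


class TestAttExchange:
    def _element(self, gid, attl, attr, i):
        from mge_atlas.integration import Element

        return Element(
            id=f"e{i}", genome_id=gid, start=attl[1], end=attr[2],
            att_left=AttSite(*attl[:1], attl[1], attl[2], "attL"),
            att_right=AttSite(*attr[:1], attr[1], attr[2], "attR"),
        )

    def test_self_consistent_pairs_no_inversion(self, rng):
        a = rand_dna(rng, 50)
        b = rand_dna(rng, 50)
        e1 = self._element("g", (a, 100, 150), (a, 900, 950), 1)
        e2 = self._element("g", (b, 2000, 2050), (b, 2900, 2950), 2)
        rep = detect_att_exchange(e1, e2)
        assert not rep.inversion_called

    def test_swapped_central_segments_called(self, rng):
        # inversion between neighbours: each element's left att matches the
        # other element's left att instead of its own right att
        a, b = rand_dna(rng, 50), rand_dna(rng, 50)
        e1 = self._element("g", (a, 100, 150), (b, 900, 950), 1)
        e2 = self._element("g", (a, 2000, 2050), (b, 2900, 2950), 2)
        rep = detect_att_exchange(e1, e2)
        assert rep.inversion_called
        assert rep.pattern == {
            "a_self": False, "b_self": False,
            "cross_LL": True, "cross_RR": True,
        }

    def test_different_genomes_error(self, rng):
        a = rand_dna(rng, 50)
        e1 = self._element("g1", (a, 100, 150), (a, 900, 950), 1)
        e2 = self._element("g2", (a, 100, 150), (a, 900, 950), 2)
        with pytest.raises(ValueError):
            detect_att_exchange(e1, e2)
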