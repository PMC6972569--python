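"""Synthetic host genomes and integrated elements with machine-readable truth.

The generator emulates the study design the analysis assumes: two diverged
archaeal host "orders" (Thermococcales-like order A, Methanococcales-like
order B), each hosting elements of one plasmid family built around a
12-gene conserved module of which 7 gene slots are universal core
(slots t26-5p, 6p, 7p, 11p, 13p, 14p, 15p).  Order A elements integrate
with a type I strategy (the integrase gene is split by the att site),
order B with type II (intact integrase mid-element); attB always overlaps
the 3' end of a tRNA gene (varied isotypes in order A, Ser with rare Leu
in order B).  One element is a gene-poor remnant (3 retained core genes,
no detectable limits), one element per order stays free (extrachromosomal).
Optional signals: a GC-skew switch plus an iterated-repeat cluster at the
replication origin, a Rep gene drawn from the packaged exemplar classes,
and CRISPR arrays whose spacers are verbatim copies of same-order element
sequence.  Every coordinate, label and protein emitted is recorded in a
truth set so the full pipeline can be round-trip tested.

Module proteins are generated by evolving random ancestral sequences down
a two-order species tree, so the deep inter-order split is encoded in
sequence divergence and the host/element tree congruence is a recoverable
property rather than an assumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .genecalling import STOP_CODONS, translate_cds
from .host_range import KNOWN_REGIONS
from .replication import load_rep_references
from .sequence_io import Feature, GenomeRecord, write_fasta, write_gff

__all__ = [
    "GeneratorConfig",
    "ElementDesign",
    "Dataset",
    "evolve_sequence",
    "implant_element",
    "implant_crispr_array",
    "generate_dataset",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARR = np.frombuffer(AA20.encode(), dtype=np.uint8)
_DNA_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

_T11 = unambiguous_dna_by_id[11]
_SYN: dict[str, list[str]] = {}
for codon, aa in sorted(_T11.forward_table.items()):
    _SYN.setdefault(aa, []).append(codon)

MODULE_SLOTS = tuple(range(4, 16))  # t26-4p .. t26-15p
CORE_SLOTS = frozenset({5, 6, 7, 11, 13, 14, 15})
ORDER_A_TRNAS = ("Arg", "Thr", "Gly", "Val", "Glu", "Tyr", "Ala")
_ANTICODON = {
    "Arg": "ACG", "Thr": "AGT", "Gly": "GCC", "Val": "AAC", "Glu": "TTC",
    "Tyr": "GTA", "Ala": "AGC", "Ser": "GCT", "Leu": "TAG", "Lys": "TTT",
    "Pro": "AGG", "Ile": "GAT",
}
FILLER_TRNAS = ("Lys", "Pro", "Ile")
# T-arm of the tRNA: a perfect 5-nt hairpin (GGTTC / GAACC) that yields the
# imperfect palindrome expected inside att sites; stop-free in all frames.
T_ARM = "GGTTCGAGAACC"
CRISPR_REPEAT = "GTTTCAGACGAACCCTTGTGGGGTTGAAGC"
# intergenic terminator: stop codons in all three frames of BOTH strands
# (and no ATG/GTG), so maximal ORFs cannot run through a gene boundary
STOP_MOTIF = "GCTAATTTAGTCTAA"


def _is_stop_motif(s: str) -> bool:
    from .genecalling import revcomp as _rc

    if "ATG" in s or "GTG" in s or s[-3:] not in STOP_CODONS:
        return False
    for t in (s, _rc(s)):
        for f in range(3):
            if not any(t[i : i + 3] in STOP_CODONS for i in range(f, len(t) - 2, 3)):
                return False
    return True


def _draw_stop_motif(rng) -> str:
    """A random 15-nt terminator with the STOP_MOTIF property.

    Drawn once per element so the terminator is not a literal sequence
    shared across elements (a shared island would create artefactual
    spacer/repeat matches between unrelated elements).
    """
    for _ in range(20_000):
        cand = "".join("ACGT"[i] for i in rng.integers(0, 4, 12)) + "TAA"
        if _is_stop_motif(cand):
            return cand
    return STOP_MOTIF


@dataclass
class GeneratorConfig:
    """Study-condition knobs; the defaults ARE the emulated design."""

    seed: int = 0
    n_hosts_per_order: int = 6
    host_length: int = 60_000
    deep_split: float = 0.08       # aa subst/site root -> each order ancestor
    within_order_branch: tuple[float, float] = (0.015, 0.035)
    within_order_depth: float = 0.08  # max root-to-leaf depth inside an order
    noncore_presence_fraction: float = 0.6   # elements carrying a non-core slot
    variable_gene_mean: float = 3.0
    att_length_range: tuple[int, int] = (44, 129)
    remnant_count: int = 1
    remnant_retained: int = 3
    rep_probs_order_a: dict = field(
        default_factory=lambda: {"t26-22p-like": 0.3, "MCM": 0.15, None: 0.55}
    )
    rep_probs_order_b: dict = field(
        default_factory=lambda: {"MCM": 0.4, "MCM-like": 0.3, None: 0.3}
    )
    ori_signal: bool = True
    crispr_rate: float = 0.5
    n_spacers: int = 4
    spacer_length: int = 35
    spacer_policy: str = "same_order_other"
    leu_target_rate: float = 0.1   # order B: tRNA-Leu instead of Ser
    transfer_rate: float = 0.0     # within-order core-module replacement
    post_implant_mutation: float = 0.0
    n_host_markers: int = 3

    def validate(self) -> None:
        rates = [
            self.noncore_presence_fraction, self.crispr_rate,
            self.leu_target_rate, self.transfer_rate,
            self.post_implant_mutation,
        ]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.deep_split < 0 or self.deep_split >= 1:
            raise ValueError("deep_split must be in [0, 1)")
        if not set(CORE_SLOTS) <= set(MODULE_SLOTS):
            raise ValueError("core slots must be module slots")
        lo, hi = self.att_length_range
        if not (20 <= lo <= hi):
            raise ValueError("bad att length range")
        if self.n_hosts_per_order < 2:
            raise ValueError("need at least 2 hosts per order")


def evolve_sequence(seq: str, subst_rate: float, seed) -> str:
    """Site-independent substitutions at the given expected rate.

    The alphabet is sniffed from the input (DNA if only ACGTN); substituted
    sites receive a uniformly random different symbol.  Deterministic per
    seed (an int or an existing numpy Generator).
    """
    if not (0.0 <= subst_rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if subst_rate == 0.0 or not seq:
        return seq
    alphabet = _DNA_ARR if set(seq) <= set("ACGTN") else _AA_ARR
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < subst_rate
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = alphabet[alphabet != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _random_protein(rng, length: int, start_with_m: bool = True) -> str:
    aa = "".join(AA20[i] for i in rng.integers(0, 20, length))
    return ("M" + aa[1:]) if start_with_m else aa


def _random_dna(rng, length: int, bias: int = 0) -> str:
    if bias == 0:
        probs = [0.25, 0.25, 0.25, 0.25]
    elif bias > 0:  # G-rich -> positive GC skew
        probs = [0.25, 0.13, 0.37, 0.25]
    else:
        probs = [0.25, 0.37, 0.13, 0.25]
    return "".join("ACGT"[i] for i in rng.choice(4, size=length, p=probs))


def _backtranslate(rng, protein: str, bias: int = 0, stop: bool = True,
                   usage: Optional[int] = None) -> str:
    """Back-translate a protein with weighted synonymous codon choice.

    ``bias`` weights codons by exp(+-1.5 (G - C)) so the coding strand
    carries a GC-skew signal while codon usage stays diverse (a
    deterministic choice would deplete reverse-strand stop codons and
    create huge spurious ORFs).  ``usage`` selects one of two opposed
    codon-usage preferences, mimicking order-specific codon bias: protein
    identity between orders is untouched but silent-site DNA identity
    drops, as it does between real archaeal orders.
    """
    out = []
    for aa in protein:
        codons = _SYN[aa]
        if len(codons) == 1:
            out.append(codons[0])
            continue
        w = np.ones(len(codons))
        if bias:
            w = w * np.exp(
                [1.5 * bias * (c.count("G") - c.count("C")) for c in codons]
            )
        if usage is not None:
            idx = np.arange(len(codons), dtype=float)
            w = w * (4.0 ** (-idx) if usage == 0 else 4.0 ** (idx - len(codons) + 1))
        out.append(codons[int(rng.choice(len(codons), p=w / w.sum()))])
    if stop:
        out.append("TAA")
    return "".join(out)


# ---------------------------------------------------------------------------
# species tree and sequence evolution


@dataclass
class _Node:
    children: list  # [( _Node | str leaf, branch_length )]


def _random_tree(rng, leaves: list[str], blen_range) -> _Node | str:
    if len(leaves) == 1:
        return leaves[0]
    order = list(rng.permutation(len(leaves)))
    k = int(rng.integers(1, len(leaves)))
    left = [leaves[i] for i in sorted(order[:k])]
    right = [leaves[i] for i in sorted(order[k:])]
    bl = lambda: float(rng.uniform(*blen_range))
    return _Node(
        children=[
            (_random_tree(rng, left, blen_range), bl()),
            (_random_tree(rng, right, blen_range), bl()),
        ]
    )


def _max_depth(node) -> float:
    if isinstance(node, str):
        return 0.0
    return max(bl + _max_depth(child) for child, bl in node.children)


def _scale_branches(node, factor: float) -> None:
    if isinstance(node, str):
        return
    node.children = [(child, bl * factor) for child, bl in node.children]
    for child, _bl in node.children:
        _scale_branches(child, factor)


def _rescale_depth(node, target_depth: float) -> None:
    """Scale branch lengths so the deepest leaf sits at ``target_depth``.

    Caps within-order divergence independently of host count: cross-order
    orthologs must stay detectable at the fixed >30% normalized-score rule,
    which bounds the total root-to-leaf path the generator may use.
    """
    depth = _max_depth(node)
    if depth > 0:
        _scale_branches(node, target_depth / depth)


def _evolve_down(node, seqs: dict[str, str], rng, out: dict) -> None:
    """Evolve a set of named proteins down a tree; fills out[leaf]."""
    if isinstance(node, str):
        out[node] = dict(seqs)
        return
    for child, blen in node.children:
        mutated = {
            name: ("M" + evolve_sequence(s[1:], blen, rng)) if s[:1] == "M"
            else evolve_sequence(s, blen, rng)
            for name, s in seqs.items()
        }
        _evolve_down(child, mutated, rng, out)


# ---------------------------------------------------------------------------
# element design and implantation


@dataclass
class ElementDesign:
    """Everything needed to materialise one element's DNA."""

    id: str
    order: str                      # "A" or "B"
    integration_type: Optional[str]  # "I", "II", or None (remnant)
    state: str                      # integrated / free / remnant
    genes: dict[str, str]           # name -> protein (module, rep, variable)
    integrase_protein: Optional[str]
    rep_class: Optional[str]
    target_trna: Optional[str]
    att_length: int
    ori_signal: bool
    host_id: Optional[str] = None
    att_in: Optional[int] = None    # tRNA-side att extent chosen with the backbone


def _gene_block(rng, design: ElementDesign, bias_for: dict[str, int],
                motif: str = STOP_MOTIF) -> tuple[str, list[tuple[str, int, int]]]:
    """Concatenate the element's ordinary genes with intergenic spacers.

    Returns (dna, [(gene name, start, end)]) with coordinates local to the
    block.  Each gene is an ATG-started CDS with stop; bias steers codon
    choice for the GC-skew signal.
    """
    parts: list[str] = []
    coords: list[tuple[str, int, int]] = []
    pos = 0
    for name in design.genes:
        # the gap ends with stops in the downstream gene's frame so maximal
        # ORFs start at the real gene start, not a chance upstream ATG
        gap = _random_dna(rng, int(rng.integers(30, 120)),
                          bias_for.get(name, 0)) + motif
        parts.append(gap)
        pos += len(gap)
        cds = _backtranslate(rng, design.genes[name], bias_for.get(name, 0),
                             usage=0 if design.order == "A" else 1)
        cds = "ATG" + cds[3:]
        parts.append(cds)
        coords.append((name, pos, pos + len(cds)))
        pos += len(cds)
    return "".join(parts), coords


def _ori_cluster(rng, bias_flip_at: bool = True) -> str:
    """An iterated-repeat cluster marking the replication origin."""
    unit = _random_dna(rng, 25)
    parts = [unit]
    for _ in range(5):
        parts.append(_random_dna(rng, 5))
        parts.append(unit)
    return "".join(parts)


def _split_genes_at_ori(design: ElementDesign) -> tuple[list[str], list[str]]:
    """Gene names before / after the origin (Rep gene kept adjacent)."""
    names = list(design.genes)
    if not design.ori_signal:
        return names, []
    rep = [n for n in names if n == "rep"]
    others = [n for n in names if n != "rep"]
    cut = max(1, (2 * len(others)) // 3)
    before = others[:cut] + rep  # ori right after the Rep gene
    after = others[cut:]
    return before, after


def _build_circle(rng, design: ElementDesign, att_seq: str) -> tuple[str, list[tuple[str, int, int, dict]], Optional[tuple[int, int]]]:
    """Materialise the element circle, linearised starting at attP.

    Returns (circle dna, feature tuples (name, start, end, attrs) local to
    the circle, ori interval or None).  For type I the att is embedded in
    the integrase CDS, so the caller must have pre-validated att_seq for
    stop-free translation (see _att_frame_clean).
    """
    before, after = _split_genes_at_ori(design)
    bias_for = {}
    if design.ori_signal:
        bias_for = {n: 1 for n in before} | {n: -1 for n in after}
    g_before = {n: design.genes[n] for n in before}
    g_after = {n: design.genes[n] for n in after}
    motif = _draw_stop_motif(rng)

    feats: list[tuple[str, int, int, dict]] = []
    ori_iv = None

    if design.integration_type == "I":
        intp = design.integrase_protein
        n_aa = intp[:120]
        c_aa = intp[160:]
        usage = 0 if design.order == "A" else 1
        pre = _backtranslate(rng, n_aa, stop=False, usage=usage)
        pre = "ATG" + pre[3:]
        pad = "GCA"[: (3 - len(att_seq) % 3) % 3]
        post = _backtranslate(rng, c_aa, stop=True, usage=usage)
        # circle starts at attP, which is the first chunk of the C fragment
        chunks = [att_seq + pad + post]
        pos = len(chunks[0])
        feats.append(("int_C", 0, pos, {"product": "integrase", "fragment": "C"}))
        d1 = ElementDesign(**{**asdict(design), "genes": g_before})
        block, coords = _gene_block(rng, d1, bias_for, motif)
        for name, s, e in coords:
            feats.append((name, pos + s, pos + e, {"product": _product(name)}))
        chunks.append(block)
        pos += len(block)
        if design.ori_signal:
            lead = motif + _random_dna(rng, 60, 1)
            cluster = _ori_cluster(rng)
            tail = _random_dna(rng, 60, -1) + motif
            chunks.append(lead + cluster + tail)
            ori_iv = (pos + len(lead), pos + len(lead) + len(cluster))
            pos += len(lead) + len(cluster) + len(tail)
        d2 = ElementDesign(**{**asdict(design), "genes": g_after})
        block, coords = _gene_block(rng, d2, bias_for, motif)
        for name, s, e in coords:
            feats.append((name, pos + s, pos + e, {"product": _product(name)}))
        chunks.append(block)
        pos += len(block)
        gap = motif + _random_dna(rng, 40, -1 if design.ori_signal else 0) + motif
        chunks.append(gap)
        pos += len(gap)
        feats.append(
            ("int_N", pos, pos + len(pre), {"product": "integrase", "fragment": "N"})
        )
        chunks.append(pre)  # ends exactly at attR after integration
        return "".join(chunks), feats, ori_iv

    # type II or remnant: att (if any) is intergenic at the circle start
    chunks = [att_seq]
    pos = len(att_seq)
    genes1 = dict(g_before)
    if design.integration_type == "II":
        # intact integrase mid-element, after the first gene block
        pass
    d1 = ElementDesign(**{**asdict(design), "genes": genes1})
    block, coords = _gene_block(rng, d1, bias_for, motif)
    for name, s, e in coords:
        feats.append((name, pos + s, pos + e, {"product": _product(name)}))
    chunks.append(block)
    pos += len(block)
    if design.integration_type == "II":
        gap = _random_dna(rng, 50, 1 if design.ori_signal else 0) + motif
        cds = _backtranslate(rng, design.integrase_protein,
                             usage=0 if design.order == "A" else 1)
        cds = "ATG" + cds[3:]
        chunks.append(gap + cds)
        feats.append(
            ("int", pos + len(gap), pos + len(gap) + len(cds), {"product": "integrase"})
        )
        pos += len(gap) + len(cds)
    if design.ori_signal:
        lead = motif + _random_dna(rng, 60, 1)
        cluster = _ori_cluster(rng)
        tail = _random_dna(rng, 60, -1) + motif
        chunks.append(lead + cluster + tail)
        ori_iv = (pos + len(lead), pos + len(lead) + len(cluster))
        pos += len(lead) + len(cluster) + len(tail)
    d2 = ElementDesign(**{**asdict(design), "genes": g_after})
    block, coords = _gene_block(rng, d2, bias_for, motif)
    for name, s, e in coords:
        feats.append((name, pos + s, pos + e, {"product": _product(name)}))
    chunks.append(block)
    pos += len(block)
    chunks.append(motif + _random_dna(rng, 50, -1 if design.ori_signal else 0))
    return "".join(chunks), feats, ori_iv


def _product(name: str) -> str:
    if name.startswith("t26-"):
        return f"{name} family protein"
    if name == "rep":
        return "replication protein"
    return "hypothetical protein"


def _att_frame_clean(att_seq: str, design: ElementDesign) -> bool:
    """For type I: the att must translate stop-free inside the integrase CDS
    (frame 0, including the straddling codon into the pad/post)."""
    pad = "GCA"[: (3 - len(att_seq) % 3) % 3]
    probe = att_seq + pad + "GCT"
    return not any(
        probe[i : i + 3] in STOP_CODONS for i in range(0, len(probe) - 2, 3)
    )


def _trna_sequence(rng, isotype: str) -> str:
    """75-nt tRNA gene: anticodon at offset 32, T-arm hairpin at offset 52."""
    ac = _ANTICODON.get(isotype, "NNN")
    body = _random_dna(rng, 75)
    seq = body[:32] + ac + body[35:52] + T_ARM + body[52 + len(T_ARM) :]
    assert len(seq) == 75
    return seq


def implant_element(
    host: GenomeRecord,
    design: ElementDesign,
    trna_target: str,
    rng: np.random.Generator,
    att_length: Optional[int] = None,
) -> tuple[GenomeRecord, dict]:
    """Integrate an element at the 3' end of a target tRNA.

    The att sequence (attB) covers the tRNA 3' terminus plus downstream
    flank; integration duplicates it as attL/attR so the tRNA gene is not
    disrupted.  For type I the integrase CDS is written split across the
    limits with the att inside its coding sequence.  Returns the new genome
    and a truth entry.  Remnant designs are inserted without att
    duplication (their limits are undetectable by construction).
    """
    if design.state == "remnant":
        block, coords = _gene_block(rng, design, {}, _draw_stop_motif(rng))
        insert = _random_dna(rng, 40) + block + _random_dna(rng, 40)
        # a remnant has lost its att pair: insert without duplication, away
        # from existing features, so its limits are undetectable by design
        occupied = sorted((f.start, f.end) for f in host.features)
        ins_at = None
        for _ in range(200):
            cand = int(rng.integers(2000, len(host.sequence) - 2000))
            if all(cand <= s or cand >= e for s, e in occupied):
                ins_at = cand
                break
        if ins_at is None:
            raise ValueError("no free backbone position for remnant insert")
        new_seq = host.sequence[:ins_at] + insert + host.sequence[ins_at:]
        new_feats = _shift_features(host.features, ins_at, len(insert))
        for name, s, e in coords:
            new_feats.append(
                Feature(
                    id=f"{design.id}.{name}", kind="CDS",
                    start=ins_at + 40 + s, end=ins_at + 40 + e,
                    strand="+", attributes={"product": _product(name)},
                )
            )
            new_feats.sort(key=lambda f: (f.start, f.end))
        genome = GenomeRecord(host.id, new_seq, host.circular, new_feats)
        truth = {
            "element_id": design.id, "host": host.id, "order": design.order,
            "state": "remnant", "span": [ins_at, ins_at + len(insert)],
            "att": None, "integrase_type": None, "target_trna": None,
            "rep_class": None, "ori": None,
            "genes": {n: [ins_at + 40 + s, ins_at + 40 + e] for n, s, e in coords},
            "circle_length": len(insert), "integrase_protein": None,
            "families": dict(design.genes),
        }
        return genome, truth

    trnas = [
        f for f in host.features
        if f.kind == "tRNA" and f.attributes.get("isotype") == trna_target
    ]
    if not trnas:
        raise ValueError(f"host {host.id} has no tRNA-{trna_target}")
    trna = trnas[0]
    L = int(att_length or design.att_length)
    att_in = design.att_in
    if att_in is None:
        att_in = int(rng.integers(30, 49))
    att_in = min(att_in, L - 5, trna.end - trna.start)
    att_out = L - att_in
    b0, b1 = trna.end - att_in, trna.end + att_out
    att_seq = host.sequence[b0:b1]

    if design.integration_type == "I" and not _att_frame_clean(att_seq, design):
        raise ValueError("att region incompatible with split-integrase frame")

    circle, feats, ori_iv = _build_circle(rng, design, att_seq)
    rest = circle[len(att_seq):]
    # keep the att boundaries crisp: a chance base match just outside either
    # repeat copy would extend the maximal direct repeat past the designed
    # att, making the implanted att length ill-defined.  Flip the flanking
    # host base (outside attB) whenever it matches the circle side.
    host_seq = host.sequence
    if b0 > 0 and host_seq[b0 - 1] == rest[-1]:
        repl = next(c for c in "ACGT" if c != rest[-1] and c != host_seq[b0 - 1])
        host_seq = host_seq[: b0 - 1] + repl + host_seq[b0:]
    if b1 < len(host_seq) and host_seq[b1] == rest[0]:
        repl = next(c for c in "ACGT" if c != rest[0] and c != host_seq[b1])
        host_seq = host_seq[:b1] + repl + host_seq[b1 + 1 :]
    # integrated: H1 + attL + rest + attR + H2  (attB duplicated)
    new_seq = host_seq[:b1] + rest + att_seq + host_seq[b1:]
    insert_len = len(rest) + L
    new_feats = _shift_features(host.features, b1, insert_len)
    attl = (b0, b1)
    attr = (b1 + len(rest), b1 + len(rest) + L)
    new_feats.append(
        Feature(id=f"{design.id}.attL", kind="att", start=attl[0], end=attl[1],
                strand="+", attributes={"role": "attL"})
    )
    new_feats.append(
        Feature(id=f"{design.id}.attR", kind="att", start=attr[0], end=attr[1],
                strand="+", attributes={"role": "attR"})
    )
    gene_truth = {}
    for name, s, e, attrs in feats:
        # circle-local offset x maps to genome position b0 + x (attP chunk
        # becomes attL; the int_N fragment ends exactly at attR start)
        g_start, g_end = b0 + s, b0 + e
        new_feats.append(
            Feature(id=f"{design.id}.{name}", kind="CDS", start=g_start,
                    end=g_end, strand="+", attributes=dict(attrs))
        )
        gene_truth[name] = [g_start, g_end]
    new_feats.sort(key=lambda f: (f.start, f.end))
    genome = GenomeRecord(host.id, new_seq, host.circular, new_feats)
    truth = {
        "element_id": design.id, "host": host.id, "order": design.order,
        "state": "integrated",
        "span": [attl[0], attr[1]],
        "att": {"left": list(attl), "right": list(attr), "sequence": att_seq},
        "integrase_type": design.integration_type,
        "target_trna": trna_target,
        "rep_class": design.rep_class,
        "ori": [b0 + ori_iv[0], b0 + ori_iv[1]] if ori_iv else None,
        "genes": gene_truth,
        "circle_length": len(circle),
        "integrase_protein": _integrase_truth(design, att_seq),
        "families": dict(design.genes),
    }
    return genome, truth


def _integrase_truth(design: ElementDesign, att_seq: str) -> Optional[str]:
    if design.integrase_protein is None:
        return None
    if design.integration_type == "II":
        return design.integrase_protein
    # type I: the att and pad codons sit inside the CDS
    n_aa = design.integrase_protein[:120]
    c_aa = design.integrase_protein[160:]
    pad = "GCA"[: (3 - len(att_seq) % 3) % 3]
    mid = translate_cds(
        (att_seq + pad + "GCT")[: (len(att_seq) + len(pad)) // 3 * 3],
        "+", initiator=False,
    ) if (len(att_seq) + len(pad)) >= 3 else ""
    # boundary codon mixing att and post belongs to the mid segment already
    return "M" + n_aa[1:] + mid + c_aa


def _shift_features(features: list[Feature], at: int, by: int) -> list[Feature]:
    out = []
    for f in features:
        if f.start >= at:
            out.append(Feature(f.id, f.kind, f.start + by, f.end + by,
                               f.strand, dict(f.attributes)))
        else:
            out.append(Feature(f.id, f.kind, f.start, f.end, f.strand,
                               dict(f.attributes)))
    return out


def implant_crispr_array(
    host: GenomeRecord,
    elements: list[tuple[str, str, str]],
    n_spacers: int,
    policy: str,
    rng: np.random.Generator,
    host_order: str = "",
    spacer_length: int = 35,
) -> tuple[GenomeRecord, list[dict]]:
    """Overwrite a backbone window with a repeat-spacer-repeat CRISPR array.

    ``elements`` lists (element id, order, circle sequence) candidates; the
    default policy restricts sources to same-order elements other than any
    hosted by this genome.  Each spacer is a verbatim copy; provenance is
    returned for the truth set.
    """
    if policy not in {"same_order_other", "any"}:
        raise ValueError(f"unknown policy {policy!r}")
    pool = [
        (eid, order, seq) for eid, order, seq in elements
        if policy == "any" or (order == host_order and not eid.startswith(host.id))
    ]
    spacer_rows: list[dict] = []
    parts = [CRISPR_REPEAT]
    for k in range(n_spacers):
        if not pool:
            break
        eid, _order, seq = pool[int(rng.integers(0, len(pool)))]
        start = int(rng.integers(0, len(seq) - spacer_length))
        spacer = seq[start : start + spacer_length]
        parts.append(spacer)
        parts.append(CRISPR_REPEAT)
        spacer_rows.append(
            {
                "id": f"{host.id}.sp{k + 1}", "host": host.id,
                "source_element": eid, "source_start": start,
                "source_end": start + spacer_length, "sequence": spacer,
            }
        )
    array = "".join(parts)
    # place away from existing features
    occupied = sorted((f.start, f.end) for f in host.features)
    pos = None
    for _ in range(200):
        cand = int(rng.integers(1000, len(host.sequence) - len(array) - 1000))
        if all(cand + len(array) <= s or cand >= e for s, e in occupied):
            pos = cand
            break
    if pos is None:
        raise ValueError("no free backbone window for CRISPR array")
    new_seq = host.sequence[:pos] + array + host.sequence[pos + len(array):]
    feats = list(host.features) + [
        Feature(id=f"{host.id}.crispr", kind="CRISPR_array", start=pos,
                end=pos + len(array), strand="+",
                attributes={"n_spacers": str(len(spacer_rows))})
    ]
    feats.sort(key=lambda f: (f.start, f.end))
    return GenomeRecord(host.id, new_seq, host.circular, feats), spacer_rows


# ---------------------------------------------------------------------------
# full dataset


@dataclass
class Dataset:
    config: GeneratorConfig
    hosts: list[GenomeRecord]
    free_elements: list[GenomeRecord]
    truth: dict
    metadata: pd.DataFrame
    spacers: list[tuple[str, str, str]]  # (id, host, sequence)
    core_ref: dict[str, str]
    int_ref: dict[str, str]
    host_markers: dict[str, dict[str, str]]

    def element_sequence(self, element_id: str) -> str:
        """Element nucleotide sequence: genome span slice or free circle."""
        t = self.truth["elements"][element_id]
        if t["host"] is None:
            for rec in self.free_elements:
                if rec.id == element_id:
                    return rec.sequence
            raise KeyError(element_id)
        host = next(h for h in self.hosts if h.id == t["host"])
        return host.sequence[t["span"][0] : t["span"][1]]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        (out / "genomes").mkdir(parents=True, exist_ok=True)
        for rec in self.hosts:
            write_fasta([rec], out / "genomes" / f"{rec.id}.fna")
            write_gff(rec, out / "genomes" / f"{rec.id}.gff3")
        write_fasta(self.free_elements, out / "free_plasmids.fna")
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        with open(out / "spacers.tsv", "w") as fh:
            fh.write("spacer_id\thost\tsequence\n")
            for sid, host, seq in self.spacers:
                fh.write(f"{sid}\t{host}\t{seq}\n")
        write_fasta(sorted(self.core_ref.items()), out / "core_ref.faa")
        write_fasta(sorted(self.int_ref.items()), out / "int_ref.faa")
        marker_rows = [
            (f"{hid}|{m}", seq)
            for hid, ms in sorted(self.host_markers.items())
            for m, seq in sorted(ms.items())
        ]
        write_fasta(marker_rows, out / "host_markers.faa")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _assign_rep_classes(rng, probs: dict, n: int) -> list[Optional[str]]:
    classes = sorted(probs, key=lambda c: (c is None, c))
    p = np.array([probs[c] for c in classes], dtype=float)
    p = p / p.sum()
    return [classes[int(i)] for i in rng.choice(len(classes), size=n, p=p)]


def generate_dataset(config: GeneratorConfig | None = None,
                     out_dir=None) -> Dataset:
    """Generate the full two-order dataset with its truth set.

    Deterministic per ``config.seed`` (byte-identical re-runs).  With
    ``out_dir`` the dataset is also written to disk (FASTA/GFF3 per host,
    free plasmids, spacer TSV, metadata TSV, reference FASTAs, truth JSON).
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_hosts_per_order

    # --- ancestral sequences -------------------------------------------------
    slot_lengths = {s: int(rng.integers(130, 260)) for s in MODULE_SLOTS}
    root_module = {
        f"t26-{s}p": _random_protein(rng, slot_lengths[s]) for s in MODULE_SLOTS
    }
    int_root = {
        "A": _random_protein(rng, 300),
        "B": _random_protein(rng, 300),
    }
    rep_refs = load_rep_references()
    rep_root = {}
    for cls in ("MCM", "MCM-like", "t26-22p-like"):
        exemplar = next(seq for _rid, c, seq in rep_refs if c == cls)
        rep_root[cls] = "M" + evolve_sequence(exemplar[1:], 0.2, rng)
    marker_root = {
        f"marker{k + 1}": _random_protein(rng, 250)
        for k in range(config.n_host_markers)
    }

    # --- species trees: per order, hosts plus one free-element lineage -------
    leaves = {}
    trees = {}
    for order in ("A", "B"):
        hosts = [f"host{order}{i + 1}" for i in range(n)]
        free = [f"pFREE_{order}1"]
        tree = _random_tree(rng, hosts + free, config.within_order_branch)
        _rescale_depth(tree, config.within_order_depth)
        trees[order] = tree
        leaves[order] = hosts + free

    # evolve everything down: deep branch to the order ancestor, then the tree
    evolved: dict[str, dict[str, str]] = {}
    for order in ("A", "B"):
        seqs = dict(root_module)
        seqs["integrase"] = int_root[order]
        for cls, s in rep_root.items():
            seqs[f"rep::{cls}"] = s
        seqs |= {f"host::{m}": s for m, s in marker_root.items()}
        ancestor = {
            name: ("M" + evolve_sequence(s[1:], config.deep_split, rng))
            for name, s in seqs.items()
        }
        _evolve_down(trees[order], ancestor, rng, evolved)

    # --- element designs -----------------------------------------------------
    all_leaf_ids = leaves["A"] + leaves["B"]
    element_of_leaf = {
        leaf: (leaf if leaf.startswith("pFREE") else f"{leaf}_IP1")
        for leaf in all_leaf_ids
    }
    n_elements = len(all_leaf_ids)

    # non-core module slots: each carried by a fixed fraction of elements
    noncore = [s for s in MODULE_SLOTS if s not in CORE_SLOTS]
    k_present = max(1, round(config.noncore_presence_fraction * n_elements))
    slot_carriers: dict[int, set[str]] = {}
    for s in noncore:
        idx = rng.choice(n_elements, size=k_present, replace=False)
        slot_carriers[s] = {all_leaf_ids[int(i)] for i in sorted(idx)}

    # within-order horizontal transfer: an element lineage adopts the module
    # proteins of another lineage of the same order
    module_source = {leaf: leaf for leaf in all_leaf_ids}
    for order in ("A", "B"):
        for leaf in leaves[order]:
            if config.transfer_rate > 0 and rng.random() < config.transfer_rate:
                others = [l for l in leaves[order] if l != leaf]
                module_source[leaf] = others[int(rng.integers(0, len(others)))]

    remnant_leaves = set()
    if config.remnant_count:
        # remnants sit in order A (mirrors the gene-poor TbaCH5_IP1-style row)
        host_leaves_a = [l for l in leaves["A"] if not l.startswith("pFREE")]
        remnant_leaves = {
            host_leaves_a[int(i)]
            for i in rng.choice(len(host_leaves_a),
                                size=min(config.remnant_count, len(host_leaves_a)),
                                replace=False)
        }

    rep_a = _assign_rep_classes(rng, config.rep_probs_order_a, len(leaves["A"]))
    rep_b = _assign_rep_classes(rng, config.rep_probs_order_b, len(leaves["B"]))
    rep_class_of = dict(zip(leaves["A"], rep_a)) | dict(zip(leaves["B"], rep_b))

    lo_att, hi_att = config.att_length_range
    designs: dict[str, ElementDesign] = {}
    retained_core = sorted(CORE_SLOTS)[: config.remnant_retained]
    for order in ("A", "B"):
        for leaf in leaves[order]:
            eid = element_of_leaf[leaf]
            is_free = leaf.startswith("pFREE")
            is_remnant = leaf in remnant_leaves
            src = evolved[module_source[leaf]]
            own = evolved[leaf]
            if is_remnant:
                genes = {f"t26-{s}p": src[f"t26-{s}p"] for s in retained_core}
                rep_cls = None
                itype = None
                state = "remnant"
            else:
                slots = [
                    s for s in MODULE_SLOTS
                    if s in CORE_SLOTS or leaf in slot_carriers[s]
                ]
                genes = {f"t26-{s}p": src[f"t26-{s}p"] for s in slots}
                rep_cls = rep_class_of[leaf]
                if rep_cls is not None:
                    genes["rep"] = own[f"rep::{rep_cls}"]
                for v in range(int(rng.poisson(config.variable_gene_mean))):
                    genes[f"var{v + 1}"] = _random_protein(
                        rng, int(rng.integers(60, 180))
                    )
                itype = "I" if order == "A" else "II"
                state = "free" if is_free else "integrated"
            if order == "A":
                target = ORDER_A_TRNAS[int(rng.integers(0, len(ORDER_A_TRNAS)))]
            else:
                target = "Leu" if rng.random() < config.leu_target_rate else "Ser"
            designs[eid] = ElementDesign(
                id=eid, order=order, integration_type=itype, state=state,
                genes=genes,
                integrase_protein=None if is_remnant else own["integrase"],
                rep_class=rep_cls,
                target_trna=None if is_remnant else target,
                att_length=int(rng.integers(lo_att, hi_att + 1)),
                ori_signal=config.ori_signal and not is_remnant,
                host_id=None if is_free else leaf,
            )

    # --- hosts, implants, truth ----------------------------------------------
    truth: dict = {"seed": config.seed, "elements": {}, "hosts": {}, "spacers": []}
    hosts_out: list[GenomeRecord] = []
    free_out: list[GenomeRecord] = []
    regions = list(KNOWN_REGIONS)
    meta_rows = []

    # free elements first (also spacer sources)
    circles: dict[str, str] = {}
    for order in ("A", "B"):
        leaf = f"pFREE_{order}1"
        design = designs[element_of_leaf[leaf]]
        att_seq = _free_att(rng, design)
        circle, feats, ori_iv = _build_circle(rng, design, att_seq)
        circles[design.id] = circle
        rec = GenomeRecord(design.id, circle, circular=True)
        free_out.append(rec)
        truth["elements"][design.id] = {
            "element_id": design.id, "host": None, "order": order,
            "state": "free", "span": [0, len(circle)],
            "att": {"left": [0, len(att_seq)], "right": None,
                    "sequence": att_seq},
            "integrase_type": design.integration_type,
            "target_trna": design.target_trna,
            "rep_class": design.rep_class,
            "ori": list(ori_iv) if ori_iv else None,
            "genes": {nm: [s, e] for nm, s, e, _a in feats},
            "circle_length": len(circle),
            "integrase_protein": _integrase_truth(design, att_seq),
            "families": dict(design.genes),
        }

    host_designs = [
        (leaf, designs[element_of_leaf[leaf]])
        for order in ("A", "B")
        for leaf in leaves[order]
        if not leaf.startswith("pFREE")
    ]
    pending: dict[str, tuple[GenomeRecord, ElementDesign]] = {}
    for leaf, design in host_designs:
        pending[leaf] = (_build_backbone(rng, config, leaf, design), design)

    # spacers are sourced from the free elements (full circles are in hand
    # before any implant, and they are bona fide same-order family members)
    spacer_pool = [
        (eid, designs[eid].order, seq) for eid, seq in sorted(circles.items())
    ]

    all_spacers: list[tuple[str, str, str]] = []
    for i, (leaf, design) in enumerate(host_designs):
        host, design = pending[leaf]
        order = design.order
        # CRISPR first (element circles of free plasmids as sources)
        if rng.random() < config.crispr_rate and spacer_pool:
            host, rows = implant_crispr_array(
                host, spacer_pool, config.n_spacers, config.spacer_policy,
                rng, host_order=order, spacer_length=config.spacer_length,
            )
            truth["spacers"].extend(rows)
            all_spacers.extend((r["id"], r["host"], r["sequence"]) for r in rows)
        if design.state == "remnant":
            genome, t = implant_element(host, design, "", rng)  # target unused
        else:
            genome, t = implant_element(host, design, design.target_trna, rng)
        if config.post_implant_mutation > 0 and t["span"]:
            s, e = t["span"]
            mutated = evolve_sequence(
                genome.sequence[s:e], config.post_implant_mutation, rng
            )
            genome = GenomeRecord(
                genome.id,
                genome.sequence[:s] + mutated + genome.sequence[e:],
                genome.circular, genome.features,
            )
        truth["elements"][t["element_id"]] = t
        region = regions[i % len(regions)]
        truth["hosts"][leaf] = {"order": order, "region": region}
        meta_rows.append({"isolate": leaf, "order": order, "region": region})
        hosts_out.append(genome)

    core_ref = {name: root_module[name] for name in sorted(root_module)
                if int(name[4:-1]) in CORE_SLOTS}
    host_markers = {
        leaf: {
            m.split("::", 1)[1]: s
            for m, s in evolved[leaf].items() if m.startswith("host::")
        }
        for order in ("A", "B")
        for leaf in leaves[order]
        if not leaf.startswith("pFREE")
    }

    ds = Dataset(
        config=config,
        hosts=hosts_out,
        free_elements=free_out,
        truth=truth,
        metadata=pd.DataFrame(meta_rows),
        spacers=all_spacers,
        core_ref=core_ref,
        int_ref={"int_A": int_root["A"], "int_B": int_root["B"]},
        host_markers=host_markers,
    )
    if out_dir is not None:
        ds.write(out_dir)
    return ds


def _free_att(rng, design: ElementDesign) -> str:
    """attP for a free element: a tRNA-tail-like sequence of the designed
    length (frame-validated for type I)."""
    for _ in range(500):
        tail = _trna_sequence(rng, design.target_trna or "Ser")[-38:]
        flank = _random_dna(rng, max(design.att_length - 38, 6))
        att = (tail + flank)[: design.att_length]
        if design.integration_type != "I" or _att_frame_clean(att, design):
            return att
    raise RuntimeError("could not draw a frame-clean att sequence")


def _build_backbone(rng, config: GeneratorConfig, host_id: str,
                    design: ElementDesign) -> GenomeRecord:
    """Random host backbone with tRNA genes (target isotype guaranteed,
    att region frame-validated for type I designs)."""
    isotypes = list(dict.fromkeys(
        ([design.target_trna] if design.target_trna else [])
        + list(ORDER_A_TRNAS[:4]) + ["Ser", "Leu"] + list(FILLER_TRNAS)
    ))[:8]
    n_trna = len(isotypes)
    length = config.host_length
    for _attempt in range(200):
        seq = _random_dna(rng, length)
        positions = np.sort(
            rng.choice(
                np.arange(3000, length - 3000, 200), size=n_trna, replace=False
            )
        )
        feats = []
        arr = list(seq)
        ok = True
        for iso, pos in zip(isotypes, positions.tolist()):
            t = _trna_sequence(rng, iso)
            arr[pos : pos + len(t)] = t
            feats.append(
                Feature(
                    id=f"{host_id}.trna_{iso}_{pos}", kind="tRNA",
                    start=pos, end=pos + len(t), strand="+",
                    attributes={
                        "isotype": iso,
                        "anticodon": _ANTICODON.get(iso, "NNN"),
                        "anticodon_start": str(pos + 32),
                        "product": f"tRNA-{iso}",
                    },
                )
            )
        seq = "".join(arr)
        if design.state != "remnant":
            trna = next(
                f for f in feats if f.attributes["isotype"] == design.target_trna
            )
            # fix the att placement together with the backbone; for type I
            # the chosen window must translate stop-free inside the
            # integrase CDS, so draw candidates until one is frame-clean
            ok = False
            hi_ai = min(49, design.att_length - 4)
            for ai in rng.permutation(np.arange(30, hi_ai)).tolist():
                window = seq[trna.end - ai : trna.end - ai + design.att_length]
                if design.integration_type != "I" or _att_frame_clean(window, design):
                    design.att_in = int(ai)
                    ok = True
                    break
        if ok:
            return GenomeRecord(host_id, seq, circular=False, features=feats)
    raise RuntimeError("could not build a frame-clean host backbone")
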