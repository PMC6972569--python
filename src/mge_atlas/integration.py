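"""Integrated-element boundary detection and integrase reconstruction.

Site-specific integration of a circular element at a chromosomal attachment
site (attB, overlapping a tRNA 3' end) duplicates the att sequence as a
direct repeat (attL/attR) flanking the element.  Element limits are
therefore found as direct repeats bracketing a cluster of core-gene
homology anchors; up to three mismatches are tolerated in the middle of the
repeat (sequence decay after integration), while both ends must be exact.

Type I integrases carry attP inside their own coding sequence, so
integration splits the gene into an N-terminal and a C-terminal fragment at
the element limits; the intact gene is reconstructed by joining the
fragment up to the att with the fragment starting at the other att copy.
Type II integrases keep an intact gene inside the element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .genecalling import START_CODONS, STOP_CODONS, OrfCall, revcomp, translate_cds
from .sequence_io import Feature, GenomeRecord

__all__ = [
    "AttSite",
    "RepeatPair",
    "Element",
    "AttExchangeReport",
    "find_direct_repeats",
    "att_sequences_match",
    "call_element_limits",
    "reconstruct_split_integrase",
    "classify_integration_type",
    "att_trna_report",
    "detect_att_exchange",
]

MIN_ATT_LENGTH = 40
MAX_MID_MISMATCHES = 3
SEARCH_WINDOW = 50_000
MAX_REPEAT_LENGTH = 250  # generously above the largest printed att (129 nt)


@dataclass(frozen=True)
class AttSite:
    """One att copy on a genome (0-based half-open)."""

    sequence: str
    start: int
    end: int
    role: str  # attL / attR / attP / attB
    mismatch_positions: tuple[int, ...] = ()

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatPair:
    """A direct repeat: two same-length copies with middle-zone mismatches."""

    start1: int
    start2: int
    length: int
    mismatch_positions: tuple[int, ...]


@dataclass
class Element:
    """A detected (or generated) integrated element."""

    id: str
    genome_id: str
    start: int
    end: int
    att_left: Optional[AttSite] = None
    att_right: Optional[AttSite] = None
    genes: list[Feature] = field(default_factory=list)
    state: str = "integrated"  # free / integrated / remnant
    integrase_type: Optional[str] = None  # I / II / None
    target_trna: Optional[str] = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class AttExchangeReport:
    element_a: str
    element_b: str
    pattern: dict[str, bool]
    inversion_called: bool


def _mid_zone(length: int) -> tuple[int, int]:
    """Central third of a repeat: mismatches are only allowed here."""
    return (length // 3, length - length // 3)


def _mismatches(s1: str, s2: str) -> list[int]:
    # N never matches anything, including another N
    return [i for i, (a, b) in enumerate(zip(s1, s2)) if a != b or a == "N"]


def att_sequences_match(s1: str, s2: str,
                        max_mid_mismatches: int = MAX_MID_MISMATCHES) -> bool:
    """True when two att sequences are identical up to middle-zone decay."""
    if len(s1) != len(s2) or not s1:
        return False
    mm = _mismatches(s1, s2)
    lo, hi = _mid_zone(len(s1))
    return len(mm) <= max_mid_mismatches and all(lo <= i < hi for i in mm)


def _valid_subrepeat(mm_flags: list[bool], min_len: int, max_mm: int):
    """Longest sub-interval of a candidate repeat that satisfies the rule.

    ``mm_flags[i]`` marks a mismatch at offset i.  Returns (offset, length)
    of the best window (longest, then leftmost) whose mismatches all fall in
    its central third with count <= max_mm, or None.
    """
    n = len(mm_flags)
    prefix = [0]
    for f in mm_flags:
        prefix.append(prefix[-1] + f)
    best = None
    for length in range(n, min_len - 1, -1):
        for off in range(0, n - length + 1):
            lo, hi = _mid_zone(length)
            # ends exact
            if prefix[off + lo] - prefix[off] or prefix[off + length] - prefix[off + hi]:
                continue
            if prefix[off + hi] - prefix[off + lo] <= max_mm:
                best = (off, length)
                break
        if best:
            break
    return best


def find_direct_repeats(window_seq: str, min_len: int = MIN_ATT_LENGTH,
                        max_mid_mismatches: int = MAX_MID_MISMATCHES,
                        max_len: int = MAX_REPEAT_LENGTH) -> list[RepeatPair]:
    """Find maximal non-overlapping direct-repeat pairs in a sequence.

    Candidate pairs are seeded by exact k-mer anchors (k = one third of the
    minimum length, so a valid repeat's exact first third always contains an
    anchor), extended with a mismatch budget, then trimmed to the longest
    window whose mismatches sit only in the central third.  Pairs are
    returned sorted by decreasing length; overlapping/duplicate hits are
    suppressed greedily from the longest down.
    """
    if min_len < 20:
        raise ValueError("min_len must be >= 20")
    seq = window_seq.upper()
    n = len(seq)
    k = max(12, min_len // 3)
    anchors: dict[str, list[int]] = {}
    for i in range(0, n - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        anchors.setdefault(kmer, []).append(i)

    candidates: list[RepeatPair] = []
    seen_pairs: set[tuple[int, int]] = set()
    for positions in anchors.values():
        if len(positions) < 2 or len(positions) > 25:
            continue  # ignore hyper-repetitive seeds (low complexity)
        for ai in range(len(positions) - 1):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                if j - i < min_len:
                    continue
                # extend exact left, then allow budgeted extension both ways
                left = 0
                while (
                    i - left - 1 >= 0
                    and j - left - 1 > i
                    and left + k < max_len
                    and seq[i - left - 1] == seq[j - left - 1]
                    and seq[i - left - 1] != "N"
                ):
                    left += 1
                start1, start2 = i - left, j - left
                if (start1, start2) in seen_pairs:
                    continue
                # budgeted rightward extension with exact-tail lookahead
                length = left + k
                budget = max_mid_mismatches
                while length < max_len and start2 + length < n and start1 + length < start2:
                    c1, c2 = seq[start1 + length], seq[start2 + length]
                    if c1 == c2 and c1 != "N":
                        length += 1
                    elif budget > 0:
                        budget -= 1
                        length += 1
                    else:
                        break
                # budgeted leftward extension as well
                while (
                    length < max_len
                    and start1 > 0
                    and start2 > start1 + 1
                    and budget > 0
                    and start2 - 1 > start1 + length
                ):
                    c1, c2 = seq[start1 - 1], seq[start2 - 1]
                    if c1 == c2 and c1 != "N":
                        break  # exact left extension already exhausted
                    budget -= 1
                    start1 -= 1
                    start2 -= 1
                    length += 1
                seen_pairs.add((start1, start2))
                flags = [
                    seq[start1 + t] != seq[start2 + t] or seq[start1 + t] == "N"
                    for t in range(length)
                ]
                fit = _valid_subrepeat(flags, min_len, max_mid_mismatches)
                if fit is None:
                    continue
                off, flen = fit
                s1, s2 = start1 + off, start2 + off
                if s2 < s1 + flen:
                    continue  # copies must not overlap each other
                mm = tuple(t for t in range(flen) if flags[off + t])
                candidates.append(RepeatPair(s1, s2, flen, mm))

    candidates.sort(key=lambda r: (-r.length, r.start1, r.start2))
    chosen: list[RepeatPair] = []
    taken: list[tuple[int, int]] = []
    for cand in candidates:
        ivs = [(cand.start1, cand.start1 + cand.length),
               (cand.start2, cand.start2 + cand.length)]
        if any(s < te and ts < e for s, e in ivs for ts, te in taken):
            continue
        chosen.append(cand)
        taken.extend(ivs)
    return chosen


def call_element_limits(
    genome: GenomeRecord,
    anchor_features: list[Feature],
    window: int = SEARCH_WINDOW,
    min_att: int = MIN_ATT_LENGTH,
    max_mid_mismatches: int = MAX_MID_MISMATCHES,
    element_id: Optional[str] = None,
) -> Optional[Element]:
    """Call an integrated element's limits around core-gene anchors.

    Searches a window flanking the anchor cluster for direct-repeat pairs
    bracketing every anchor; among bracketing pairs the longest repeat, then
    the smallest span, wins.  Returns None when no bracketing pair exists
    ("no detectable limits").
    """
    if not anchor_features:
        raise ValueError("no anchor features supplied")
    by_strand: dict[str, list[Feature]] = {}
    for f in anchor_features:
        by_strand.setdefault(f.strand, []).append(f)
    if len(by_strand) == 2:
        spans = [
            (min(f.start for f in fs), max(f.end for f in fs))
            for fs in by_strand.values()
        ]
        gap = max(spans[0][0], spans[1][0]) - min(spans[0][1], spans[1][1])
        if gap > window:
            raise ValueError(
                "anchors on both strands form inconsistent clusters "
                f"(strand spans {spans[0]} and {spans[1]})"
            )
    span_start = min(f.start for f in anchor_features)
    span_end = max(f.end for f in anchor_features)
    lo = max(0, span_start - window)
    hi = min(len(genome.sequence), span_end + window)
    region = genome.sequence[lo:hi]
    repeats = find_direct_repeats(region, min_att, max_mid_mismatches)
    bracketing = [
        r
        for r in repeats
        if lo + r.start1 + r.length <= span_start and lo + r.start2 >= span_end
    ]
    if not bracketing:
        return None
    bracketing.sort(key=lambda r: (-r.length, r.start2 - r.start1, r.start1))
    best = bracketing[0]
    attl_start = lo + best.start1
    attr_start = lo + best.start2
    att_left = AttSite(
        sequence=genome.sequence[attl_start : attl_start + best.length],
        start=attl_start,
        end=attl_start + best.length,
        role="attL",
        mismatch_positions=best.mismatch_positions,
    )
    att_right = AttSite(
        sequence=genome.sequence[attr_start : attr_start + best.length],
        start=attr_start,
        end=attr_start + best.length,
        role="attR",
        mismatch_positions=best.mismatch_positions,
    )
    return Element(
        id=element_id or f"{genome.id}_IP",
        genome_id=genome.id,
        start=att_left.start,
        end=att_right.end,
        att_left=att_left,
        att_right=att_right,
        state="integrated",
    )


def _try_join(genome_seq: str, n_side_end: int, c_side_start: int,
              search_back: int, max_protein: int) -> Optional[tuple[int, int, str, str]]:
    """Try to join an N-terminal CDS ending at ``n_side_end`` with a
    C-terminal CDS starting at ``c_side_start``.

    Scans candidate ATG/GTG starts upstream of the N-side boundary; the
    reading frame fixed by the N fragment must run through the C fragment to
    a stop with no internal stop.  Returns (n_start, c_end, start_codon,
    protein) or None.
    """
    for n_start in range(max(0, n_side_end - search_back), n_side_end - 2):
        codon = genome_seq[n_start : n_start + 3]
        if codon not in START_CODONS:
            continue
        n_len = n_side_end - n_start
        if n_len < 30:
            continue
        n_frag = genome_seq[n_start : n_start + (n_len // 3) * 3]
        if any(
            n_frag[i : i + 3] in STOP_CODONS for i in range(0, len(n_frag), 3)
        ):
            continue
        # remainder of a codon crossing the junction
        tail = n_len % 3
        joined = genome_seq[n_start:n_side_end]
        c_pos = c_side_start
        # walk the C side codon by codon, honouring the junction offset
        limit = c_side_start + max_protein * 3
        carry = joined[-tail:] if tail else ""
        cursor = c_pos
        cds_c = carry
        stop_at = None
        while cursor < min(len(genome_seq), limit):
            cds_c += genome_seq[cursor]
            cursor += 1
            if len(cds_c) % 3 == 0:
                if cds_c[-3:] in STOP_CODONS:
                    stop_at = cursor
                    break
        if stop_at is None:
            continue
        full = joined[: len(joined) - tail] + cds_c
        try:
            protein = translate_cds(full, "+", initiator=True)
        except ValueError:
            continue
        return n_start, stop_at, codon, protein
    return None


def reconstruct_split_integrase(
    genome: GenomeRecord,
    att_left: AttSite,
    att_right: AttSite,
    int_hits: list[tuple[int, int]],
    search_back: int = 3000,
    max_protein: int = 1500,
) -> OrfCall:
    """Reconstruct a type I integrase split across the element limits.

    The N-terminal CDS runs from a start codon to the last codon before one
    att copy; the C-terminal CDS runs from the first codon of the other att
    copy to a stop.  Both join orientations and both strands are attempted;
    hits to the integrase reference (``int_hits``, genome intervals) must
    flank the limits on both sides.  If an intact integrase ORF already lies
    between the atts it is returned unchanged.
    """
    if not int_hits:
        raise ValueError("no integrase homology hits supplied")
    seq = genome.sequence
    min_protein = 100  # a genuine tyrosine recombinase is far longer

    # forward gene: N fragment inside the element ending at attR,
    # C fragment starting at attL running into the element
    res = _try_join(seq, att_right.start, att_left.start, search_back, max_protein)
    if res is not None and len(res[3]) >= min_protein:
        n_start, c_end, codon, protein = res
        return OrfCall(n_start, c_end, "+", codon, protein)
    # reverse-strand gene: mirror the construction
    rc = revcomp(seq)
    n = len(seq)
    r_attl_start = n - att_right.end  # attR becomes the left copy on rc
    r_attr_start = n - att_left.end
    res = _try_join(rc, r_attr_start + len(att_left), r_attl_start + len(att_left),
                    search_back, max_protein)
    if res is not None and len(res[3]) >= min_protein:
        n_start, c_end, codon, protein = res
        return OrfCall(n - c_end, n - n_start, "-", codon, protein)

    # no split gene: an intact gene between the atts needs no reconstruction
    inner = [
        h for h in int_hits if h[0] >= att_left.end and h[1] <= att_right.start
    ]
    for h in inner:
        for strand in "+-":
            orf = _intact_orf_covering(seq, h, strand)
            if orf is not None:
                return orf
    raise ValueError("no matching open reading frames")


def _intact_orf_covering(seq: str, hit: tuple[int, int], strand: str):
    """Return the intact ORF containing ``hit`` on ``strand``, if any."""
    from .genecalling import find_orfs

    lo = max(0, hit[0] - 2000)
    hi = min(len(seq), hit[1] + 2000)
    for orf in find_orfs(seq[lo:hi], min_aa=80, circular=False):
        if orf.strand == strand and lo + orf.start <= hit[0] and lo + orf.end >= hit[1]:
            return OrfCall(lo + orf.start, lo + orf.end, orf.strand,
                           orf.start_codon, orf.protein)
    return None


def classify_integration_type(element: Element) -> Optional[str]:
    """Classify the element's integration strategy.

    Type I: an att copy lies inside the integrase coding sequence (the gene
    is split across the limits).  Type II: an intact integrase gene lies
    strictly between the att sites.  None: no integrase (remnant).
    """
    int_genes = [
        g
        for g in element.genes
        if g.kind == "CDS"
        and "integrase" in g.attributes.get("product", "").lower()
    ]
    if not int_genes:
        return None
    att_ivs = [
        (a.start, a.end)
        for a in (element.att_left, element.att_right)
        if a is not None
    ]
    split = False
    for g in int_genes:
        if g.attributes.get("fragment") in {"N", "C"}:
            split = True
            continue
        if any(g.start < e and s < g.end for s, e in att_ivs):
            split = True
            continue
        if att_ivs and element.att_left.end <= g.start and g.end <= element.att_right.start:
            return "II"
        if not att_ivs:
            return "II"
    return "I" if split else None


def att_trna_report(element: Element, trna_features: list[Feature]) -> dict:
    """Relate an element's att sites to the tRNA gene they overlap.

    attB sites of this family sit at the 3' terminus of a tRNA gene, often
    including the anticodon; a conserved imperfect palindrome in the att
    corresponds to the T-stems of the tRNA T-arm.
    """
    report = {
        "element_id": element.id,
        "target_trna": None,
        "anticodon_included": None,
        "overlap_length": 0,
        "t_stem_palindrome": None,
        "att_role": None,
    }
    atts = [a for a in (element.att_left, element.att_right) if a is not None]
    best = None
    for att in atts:
        for trna in trna_features:
            if trna.kind != "tRNA":
                continue
            ov = min(att.end, trna.end) - max(att.start, trna.start)
            if ov <= 0:
                continue
            # the att must cover the tRNA 3' terminus
            three_prime = trna.end - 1 if trna.strand == "+" else trna.start
            if not (att.start <= three_prime < att.end):
                continue
            if best is None or ov > best[0]:
                best = (ov, att, trna)
    if best is None:
        return report
    ov, att, trna = best
    report["overlap_length"] = ov
    report["target_trna"] = trna.attributes.get("isotype")
    report["att_role"] = att.role
    ac_start = trna.attributes.get("anticodon_start")
    if ac_start is not None:
        ac_start = int(ac_start)
        report["anticodon_included"] = (
            att.start <= ac_start and ac_start + 3 <= att.end
        )
    report["t_stem_palindrome"] = _has_imperfect_palindrome(att.sequence)
    return report


def _has_imperfect_palindrome(seq: str, min_arm: int = 5,
                              max_mismatches: int = 1) -> bool:
    """Detect a short inverted repeat (hairpin) within the att sequence."""
    n = len(seq)
    for arm in range(min_arm, 13):
        for i in range(0, n - 2 * arm + 1):
            left = seq[i : i + arm]
            for j in range(i + arm, n - arm + 1):
                right = revcomp(seq[j : j + arm])
                mm = sum(1 for a, b in zip(left, right) if a != b or a == "N")
                if mm <= max_mismatches:
                    return True
    return False


def detect_att_exchange(element_a: Element, element_b: Element,
                        max_mid_mismatches: int = MAX_MID_MISMATCHES) -> AttExchangeReport:
    """Flag an inversion between two co-integrated elements by att identity.

    Normally attL matches attR within each element.  After an inversion
    between two neighbouring integrated elements, within-element identity
    fails while attL(A) matches attL(B) and attR(A) matches attR(B).
    """
    if element_a.genome_id != element_b.genome_id:
        raise ValueError("elements are on different genomes")
    for el in (element_a, element_b):
        if el.att_left is None or el.att_right is None:
            raise ValueError(f"element {el.id} has no called att pair")
    m = lambda x, y: att_sequences_match(x.sequence, y.sequence, max_mid_mismatches)
    pattern = {
        "a_self": m(element_a.att_left, element_a.att_right),
        "b_self": m(element_b.att_left, element_b.att_right),
        "cross_LL": m(element_a.att_left, element_b.att_left),
        "cross_RR": m(element_a.att_right, element_b.att_right),
    }
    inversion = (
        not pattern["a_self"]
        and not pattern["b_self"]
        and pattern["cross_LL"]
        and pattern["cross_RR"]
    )
    return AttExchangeReport(element_a.id, element_b.id, pattern, inversion)
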