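"""Minimal ORF calling and translation.

Open reading frames run from an ATG or GTG start to the first in-frame stop
(TAA/TAG/TGA), on both strands, optionally across the junction of a circular
sequence.  Translation follows bacterial/archaeal table 11 conventions; an
initiator GTG is read as methionine.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .sequence_io import GenomeRecord

__all__ = ["OrfCall", "find_orfs", "translate_cds", "revcomp"]

START_CODONS = {"ATG", "GTG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}
_TABLE11 = unambiguous_dna_by_id[11]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class OrfCall:
    """One called ORF, located on the forward coordinate system.

    ``start``/``end`` are 0-based half-open forward-strand coordinates of the
    full CDS including the stop codon.  On circular sequences ``end`` may
    exceed the sequence length (the ORF wraps the junction).
    """

    start: int
    end: int
    strand: str
    start_codon: str
    protein: str

    def __len__(self) -> int:
        return self.end - self.start


def translate_cds(dna: str, strand: str = "+", initiator: bool = True,
                  partial: bool = False) -> str:
    """Translate a CDS (stop codon optional) into protein.

    With ``initiator`` a leading GTG is translated as M; without, the codon
    table value (V) is used.  An internal stop is an error unless ``partial``.
    """
    if strand == "-":
        dna = revcomp(dna)
    if len(dna) % 3:
        raise ValueError(f"CDS length {len(dna)} not divisible by 3")
    codons = [dna[i : i + 3] for i in range(0, len(dna), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    aa = []
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            if not partial:
                raise ValueError(f"internal stop codon at codon {i}")
            aa.append("*")
            continue
        if "N" in codon:
            aa.append("X")
            continue
        aa.append(_TABLE11.forward_table[codon])
    if aa and initiator and dna[:3] in START_CODONS:
        aa[0] = "M"
    return "".join(aa)


def _scan_strand(seq: str, n: int, min_aa: int, strand: str, circular: bool):
    """Yield maximal ORFs on one strand of ``seq`` (already oriented 5'->3')."""
    # on circular input, seq is the doubled sequence and n the true length
    limit = len(seq)
    for frame in range(3):
        start = None
        start_codon = None
        i = frame
        while i + 3 <= limit:
            codon = seq[i : i + 3]
            if start is None:
                if codon in START_CODONS:
                    if circular and i >= n:
                        break  # starts in the doubled copy are duplicates
                    start = i
                    start_codon = codon
            elif codon in STOP_CODONS:
                end = i + 3
                n_aa = (end - start) // 3 - 1
                if n_aa >= min_aa and (not circular or end - start <= n):
                    yield start, end, strand, start_codon
                start = None
            i += 3


def find_orfs(genome: GenomeRecord | str, min_aa: int = 50,
              circular: bool | None = None) -> list[OrfCall]:
    """Find all maximal ORFs of at least ``min_aa`` residues on both strands.

    Maximal means each stop codon terminates at most one ORF per frame (the
    one with the 5'-most start).  Coordinates are reported on the forward
    strand of the input; wrap-around ORFs on circular input keep ``end``
    greater than the sequence length.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if isinstance(genome, GenomeRecord):
        seq = genome.sequence
        if circular is None:
            circular = genome.circular
    else:
        seq = genome.upper()
        circular = bool(circular)
    n = len(seq)
    scan_f = seq + seq if circular else seq
    scan_r = revcomp(scan_f)

    orfs: list[OrfCall] = []
    for start, end, strand, sc in _scan_strand(scan_f, n, min_aa, "+", circular):
        prot = translate_cds(scan_f[start:end], "+")
        orfs.append(OrfCall(start % n if circular else start,
                            (start % n) + (end - start) if circular else end,
                            strand, sc, prot))
    for start, end, strand, sc in _scan_strand(scan_r, n, min_aa, "-", circular):
        # map back to forward coordinates: position p in scan_r corresponds to
        # forward position len(scan_f) - p
        f_start = len(scan_f) - end
        f_end = len(scan_f) - start
        prot = translate_cds(scan_r[start:end], "+")
        if circular:
            f_start %= n
            f_end = f_start + (end - start)
        orfs.append(OrfCall(f_start, f_end, strand, sc, prot))

    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    # circular doubling can still produce the same wrap ORF twice
    seen, out = set(), []
    for o in orfs:
        key = (o.start, o.end, o.strand)
        if key not in seen:
            seen.add(key)
            out.append(o)
    return out
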