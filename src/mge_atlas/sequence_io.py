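"""Readers and writers for the external formats used across the pipeline.

All coordinates are converted at this boundary: files on disk (GFF3, the
packaged element tables) use 1-based inclusive coordinates, everything in
memory is 0-based half-open.  The packaged reference tables list the known
members of the pT26-2 plasmid family (29 elements integrated in, or carried
free by, Thermococcales and Methanococcales) together with their conserved
features; they are shipped as TSV fixtures with a checksum file.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import dendropy
from Bio import SeqIO
from gffutils.feature import feature_from_line

__all__ = [
    "Feature",
    "GenomeRecord",
    "ElementTableRow",
    "FeatureTableRow",
    "ALIASES",
    "canonical_id",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "load_reference_tables",
    "write_newick",
    "read_newick",
]

FEATURE_KINDS = {"CDS", "tRNA", "CRISPR_array", "repeat_region", "att"}

# One element can appear under several printed spellings; the canonical id is
# the Table 3 spelling.  Maps alias -> canonical.
ALIASES = {
    "pGE2": "PabGE2_IP2",
    "PabGE2_IP1": "PabGE2_IP2",
    "pGE2 = PabGE2_IP1": "PabGE2_IP2",
    "MMPV1": "MmaS2_IP",
    "MMPV1 = MmaS2_IP": "MmaS2_IP",
    "TceDSM17994_IP1": "TceDSMA7994_IP1",
    "PchGC74_IP1": "PchCG74_IP1",
}


def canonical_id(element_id: str) -> str:
    """Resolve a printed element name to its canonical spelling."""
    return ALIASES.get(element_id.strip(), element_id.strip())


@dataclass
class Feature:
    """A located annotation on a genome (internal 0-based half-open)."""

    id: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A host or plasmid nucleotide sequence with its features."""

    id: str
    sequence: str
    circular: bool = False
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"record {self.id!r}: non-DNA characters {sorted(bad)}")
        for f in self.features:
            self._check_feature(f)

    def _check_feature(self, f: Feature) -> None:
        if f.end > len(self.sequence) and not f.attributes.get("wraps_origin"):
            raise ValueError(
                f"feature {f.id!r} interval [{f.start}, {f.end}) outside "
                f"genome {self.id!r} of length {len(self.sequence)}"
            )

    def add_feature(self, f: Feature) -> None:
        self._check_feature(f)
        self.features.append(f)

    def __len__(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int) -> str:
        """Slice the genome; on circular genomes end may wrap past length."""
        n = len(self.sequence)
        if end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise ValueError("interval beyond end of linear genome")
        return self.sequence[start:] + self.sequence[: end - n]


@dataclass
class ElementTableRow:
    """One row of the packaged element list (printed coordinates kept 1-based)."""

    element_id: str
    host: str
    integration_start: Optional[int]
    integration_end: Optional[int]
    att_length: Optional[int | tuple[int, int]]
    state: Optional[str]
    accession: Optional[str]
    reference: str


@dataclass
class FeatureTableRow:
    """One row of the packaged conserved-feature table."""

    element_id: str
    relative_core_size: int
    replication: Optional[str]
    ori_count: int
    integrase_type: Optional[str]
    target_trna: Optional[str]


def read_fasta(path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA into GenomeRecords, uppercasing sequences.

    RNA input (U bases) is rejected; duplicate ids and empty files are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out, seen = [], set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "U" in seq:
            raise ValueError(f"record {rec.id!r} looks like RNA (contains U)")
        out.append(GenomeRecord(id=rec.id, sequence=seq))
    return out


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid = rec.id if hasattr(rec, "id") else rec[0]
            seq = rec.sequence if hasattr(rec, "sequence") else rec[1]
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_GFF_KIND = {
    "tRNA": "tRNA",
    "CDS": "CDS",
    "CRISPR_array": "CRISPR_array",
    "repeat_region": "repeat_region",
    "att": "att",
    "attachment_site": "att",
    "direct_repeat": "repeat_region",
}


def read_gff(path, genome: GenomeRecord) -> list[Feature]:
    """Read GFF3 features for one genome, converting to internal coordinates.

    tRNA isotype/anticodon are pulled from the attribute column (either
    explicit keys or a ``product=tRNA-Xxx`` value).
    """
    feats: list[Feature] = []
    n = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gf = feature_from_line(line)
            if gf.seqid != genome.id:
                raise ValueError(
                    f"GFF seqid {gf.seqid!r} does not match genome {genome.id!r}"
                )
            kind = _GFF_KIND.get(gf.featuretype)
            if kind is None:
                continue
            attrs = {k: v[0] for k, v in gf.attributes.items() if v}
            if kind == "tRNA":
                product = attrs.get("product", "")
                m = re.match(r"tRNA[-_](\w{3})", product)
                if "isotype" not in attrs and m:
                    attrs["isotype"] = m.group(1)
            start, end = gf.start - 1, gf.end  # 1-based inclusive -> half-open
            if end > len(genome.sequence):
                raise ValueError(
                    f"feature at {gf.start}..{gf.end} beyond genome "
                    f"{genome.id!r} length {len(genome.sequence)}"
                )
            n += 1
            feats.append(
                Feature(
                    id=attrs.get("ID", f"{genome.id}.f{n}"),
                    kind=kind,
                    start=start,
                    end=end,
                    strand=gf.strand if gf.strand in "+-" else "+",
                    attributes=attrs,
                )
            )
    return feats


def write_gff(genome: GenomeRecord, path) -> None:
    """Write a genome's features as GFF3 (coordinates back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome.sequence)}\n")
        for f in genome.features:
            attrs = ";".join(
                [f"ID={f.id}"]
                + [f"{k}={v}" for k, v in sorted(f.attributes.items()) if k != "ID"]
            )
            fh.write(
                "\t".join(
                    [
                        genome.id,
                        "mge_atlas",
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def _dash_none(value: str) -> Optional[str]:
    value = value.strip()
    return None if value in {"", "-", "–"} else value


def _parse_location(text: str) -> tuple[Optional[int], Optional[int]]:
    text = text.strip()
    if text.lower().startswith("no detectable"):
        return None, None
    lo, hi = text.replace(",", "").split("-")
    return int(lo), int(hi)


def _parse_att_length(text: str):
    text = text.strip()
    if text in {"-", "–", ""}:
        return None
    if "/" in text:
        a, b = text.split("/")
        return (int(a), int(b))
    return int(text)


def _data_path(name: str) -> Path:
    return Path(resources.files("mge_atlas").joinpath("data", name))


def load_reference_tables() -> tuple[list[ElementTableRow], list[FeatureTableRow]]:
    """Load the packaged element and conserved-feature tables.

    The fixtures are verified against a packaged SHA-256 checksum file before
    parsing; any edit to the fixtures is an error, not a silent change.
    """
    checks = json.loads(_data_path("checksums.json").read_text())
    for fname, want in checks.items():
        got = hashlib.sha256(_data_path(fname).read_bytes()).hexdigest()
        if got != want:
            raise ValueError(f"fixture {fname} checksum mismatch")

    element_rows: list[ElementTableRow] = []
    lines = _data_path("table2_elements.tsv").read_text().rstrip("\n").split("\n")
    for line in lines[1:]:
        el, host, loc, att, state, acc, ref = line.split("\t")
        start, end = _parse_location(loc)
        element_rows.append(
            ElementTableRow(
                element_id=el.strip(),
                host=host.strip(),
                integration_start=start,
                integration_end=end,
                att_length=_parse_att_length(att),
                state=_dash_none(state),
                accession=_dash_none(acc),
                reference=ref.strip(),
            )
        )

    feature_rows: list[FeatureTableRow] = []
    lines = _data_path("table3_features.tsv").read_text().rstrip("\n").split("\n")
    for line in lines[1:]:
        name, core, rep, ori, itype, trna = line.split("\t")
        rep = _dash_none(rep)
        if rep is not None:
            rep = {"T26-22p like": "t26-22p-like", "MCM like": "MCM-like"}.get(rep, rep)
        ori = ori.strip()
        itype_n = _dash_none(itype)
        if itype_n is not None:
            itype_n = itype_n.replace("Type ", "")
        trna_n = _dash_none(trna)
        if trna_n is not None:
            trna_n = trna_n.replace("tRNA-", "")
        feature_rows.append(
            FeatureTableRow(
                element_id=name.strip(),
                relative_core_size=int(core),
                replication=rep,
                ori_count=0 if ori.lower() == "not found" else int(ori),
                integrase_type=itype_n,
                target_trna=trna_n,
            )
        )

    if len(element_rows) != 29 or len(feature_rows) != 29:
        raise ValueError(
            f"expected 29 rows per table, got {len(element_rows)} / {len(feature_rows)}"
        )
    return element_rows, feature_rows


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree as Newick with branch lengths."""
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)
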