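"""CRISPR-spacer host-range mapping and prevalence summaries.

A CRISPR spacer matching an element sequence records a past encounter
between that host lineage and the element.  Spacers are matched by
ungapped (Hamming) scanning at full spacer length on both strands with a
small mismatch allowance; N never matches.  Per-order and per-region
summaries mirror the prevalence bookkeeping of the family survey (genomes
with an element, with a spacer against the family, or both, combined by
inclusion-exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genecalling import revcomp

__all__ = [
    "SpacerMatch",
    "match_spacers",
    "prevalence_summary",
    "region_summary",
    "cross_order_fraction",
]

DEFAULT_MAX_MISMATCHES = 2
KNOWN_REGIONS = (
    "East Pacific Ocean Ridge",
    "Gulf of Mexico",
    "North Atlantic Ridge",
    "Vulcano Island",
    "North West Pacific Ocean Ridges",
    "Oceania",
)


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    source_host: str
    element_id: str
    position: int
    strand: str
    mismatches: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _scan_one(spacer: np.ndarray, target: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """All ungapped occurrences of ``spacer`` in ``target`` with <= max_mm
    mismatches (N never matches)."""
    m, n = len(spacer), len(target)
    if m > n:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(target, m)
    is_n = (windows == ord("N")) | (spacer == ord("N"))
    mm = ((windows != spacer) | is_n).sum(axis=1)
    hits = np.nonzero(mm <= max_mm)[0]
    return [(int(p), int(mm[p])) for p in hits]


def match_spacers(
    spacers: list[tuple[str, str, str]],
    element_seqs: dict[str, str],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> list[SpacerMatch]:
    """Match spacers (id, source host, sequence) against element sequences.

    Both strands are scanned; the match must cover the full spacer length.
    """
    matches: list[SpacerMatch] = []
    targets = {
        eid: (_encode(seq), _encode(revcomp(seq)), len(seq))
        for eid, seq in element_seqs.items()
    }
    for sid, host, sseq in spacers:
        if not (20 <= len(sseq) <= 60):
            raise ValueError(f"spacer {sid!r} length {len(sseq)} outside 20-60 nt")
        sp = _encode(sseq)
        for eid, (fwd, rev, n) in sorted(targets.items()):
            for pos, mm in _scan_one(sp, fwd, max_mismatches):
                matches.append(SpacerMatch(sid, host, eid, pos, "+", mm))
            for pos, mm in _scan_one(sp, rev, max_mismatches):
                # report on the forward coordinate system
                matches.append(
                    SpacerMatch(sid, host, eid, n - pos - len(sseq), "-", mm)
                )
    matches.sort(key=lambda m: (m.spacer_id, m.element_id, m.position, m.strand))
    return matches


def prevalence_summary(
    isolates: pd.DataFrame,
    element_hosts: set[str],
    spacer_hosts: set[str],
) -> pd.DataFrame:
    """Per-order prevalence of elements, spacers and both.

    ``isolates`` needs columns ``isolate`` and ``order`` (missing order ->
    "unassigned").  Percentages are 100 x count / total to one decimal; the
    union uses inclusion-exclusion.  With zero isolates in an order the
    percentages are reported as None.
    """
    df = isolates.copy()
    df["order"] = df.get("order", pd.Series(dtype=str)).fillna("unassigned")
    df.loc[df["order"].astype(str).str.strip() == "", "order"] = "unassigned"
    rows = []
    for order, sub in df.groupby("order", sort=True):
        names = set(sub["isolate"])
        n = len(names)
        with_el = len(names & element_hosts)
        with_sp = len(names & spacer_hosts)
        with_both = len(names & element_hosts & spacer_hosts)
        union = with_el + with_sp - with_both
        pct = lambda k: round(100.0 * k / n, 1) if n else None
        rows.append(
            {
                "order": order,
                "n_genomes": n,
                "with_element": with_el,
                "with_spacer": with_sp,
                "with_both": with_both,
                "union": union,
                "pct_element": pct(with_el),
                "pct_spacer": pct(with_sp),
                "pct_both": pct(with_both),
                "pct_union": pct(union),
            }
        )
    return pd.DataFrame(rows)


def region_summary(
    isolate_metadata: pd.DataFrame,
    element_hosts: set[str],
    spacer_hosts: set[str],
    known_regions: tuple[str, ...] = KNOWN_REGIONS,
) -> pd.DataFrame:
    """Per-region counts; regions outside the configured six go to "other"."""
    df = isolate_metadata.copy()
    region = df.get("region", pd.Series(dtype=str)).fillna("other")
    df["region"] = [r if r in known_regions else "other" for r in region]
    rows = []
    for reg, sub in df.groupby("region", sort=True):
        names = set(sub["isolate"])
        rows.append(
            {
                "region": reg,
                "n_isolates": len(names),
                "with_element": len(names & element_hosts),
                "with_spacer": len(names & spacer_hosts),
                "with_both": len(names & element_hosts & spacer_hosts),
            }
        )
    return pd.DataFrame(rows)


def cross_order_fraction(
    matches: list[SpacerMatch],
    host_order: dict[str, str],
    element_order: dict[str, str],
) -> Optional[float]:
    """Fraction of spacer matches whose spacer-source order differs from the
    matched element's host order (None with no matches)."""
    if not matches:
        return None
    cross = sum(
        1
        for m in matches
        if host_order.get(m.source_host) != element_order.get(m.element_id)
    )
    return cross / len(matches)
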