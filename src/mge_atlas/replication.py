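"""Replication-origin prediction and Rep-protein classification.

Two complementary origin predictors are combined: (i) cumulative GC skew,
whose extrema mark the replication origin/terminus of theta-replicating
replicons, and (ii) repeat-rich-region scanning (origins typically carry
iterated short repeats).  Agreeing predictions merge into one origin call;
disagreeing successful predictions yield two candidate origins; if neither
method fires the origin is "not found".

Rep proteins are classified by best normalized-score hit against a packaged
reference set of exemplars for the three classes seen in this plasmid
family: MCM (replicative helicase recruited from the host), a distantly
related MCM-like family, and the t26-22p-like P-loop NTPase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genecalling import revcomp
from .homology_core import DEFAULT_BDBH_THRESHOLD, raw_score, self_score
from .sequence_io import _data_path, read_fasta

__all__ = [
    "SkewProfile",
    "OriPrediction",
    "gc_skew_profile",
    "skew_ori_candidate",
    "repeat_density_profile",
    "repeat_ori_candidate",
    "call_ori",
    "load_rep_references",
    "classify_rep_protein",
]

DEFAULT_WINDOW = 500
DEFAULT_STEP = 100
DEFAULT_K = 10
DEFAULT_Z_THRESHOLD = 3.0
DEFAULT_AGREE_DISTANCE = 2_000
DEFAULT_SKEW_SHIFT_THRESHOLD = 0.10


@dataclass
class SkewProfile:
    positions: np.ndarray  # window centers (bp)
    skew: np.ndarray  # per-window (G - C) / (G + C)
    cumulative: np.ndarray


@dataclass(frozen=True)
class OriPrediction:
    method: str  # "skew" or "repeat"
    start: int
    end: int
    statistic: float

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def gc_skew_profile(seq: str, window: int = DEFAULT_WINDOW,
                    step: int = DEFAULT_STEP, circular: bool = False) -> SkewProfile:
    """Windowed GC skew and its cumulative sum.

    Windows without any G or C score 0.  For circular sequences the windows
    wrap past the end, so the cumulative series is origin-independent up to
    an additive constant and a rotation.
    """
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    if window > len(seq):
        raise ValueError("window larger than sequence")
    seq = seq.upper()
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_g = (arr == ord("G")).astype(np.int32)
    is_c = (arr == ord("C")).astype(np.int32)
    if circular:
        is_g = np.concatenate([is_g, is_g[: window - 1]])
        is_c = np.concatenate([is_c, is_c[: window - 1]])
        starts = np.arange(0, len(seq), step)
    else:
        starts = np.arange(0, len(seq) - window + 1, step)
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])
    g = cg[starts + window] - cg[starts]
    c = cc[starts + window] - cc[starts]
    denom = g + c
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(denom > 0, (g - c) / np.maximum(denom, 1), 0.0)
    centers = starts + window // 2
    return SkewProfile(centers, skew, np.cumsum(skew))


def skew_ori_candidate(profile: SkewProfile,
                       shift_threshold: float = DEFAULT_SKEW_SHIFT_THRESHOLD,
                       window: int = DEFAULT_WINDOW) -> Optional[OriPrediction]:
    """Origin candidate at the extremum of the cumulative skew.

    Both the maximum and the minimum of the cumulative series are candidate
    switch points; the one with the larger mean-skew shift between its two
    sides wins.  The call succeeds only when that shift magnitude reaches
    ``shift_threshold`` (guards against calling origins on flat profiles).
    """
    cum = profile.cumulative
    if len(cum) < 4:
        return None
    best = None
    for idx in (int(np.argmax(cum)), int(np.argmin(cum))):
        if idx < 1 or idx > len(cum) - 2:
            continue
        before = float(np.mean(profile.skew[: idx + 1]))
        after = float(np.mean(profile.skew[idx + 1 :]))
        shift = abs(after - before)
        if best is None or shift > best[0]:
            best = (shift, idx)
    if best is None or best[0] < shift_threshold:
        return None
    shift, idx = best
    pos = int(profile.positions[idx])
    return OriPrediction("skew", max(0, pos - window // 2), pos + window // 2, shift)


def repeat_density_profile(seq: str, k: int = DEFAULT_K,
                           window: int = DEFAULT_WINDOW) -> tuple[np.ndarray, np.ndarray]:
    """Per-window density of repeated k-mers, as z-scores.

    A position contributes when its k-mer (or that k-mer's reverse
    complement) occurs at least twice in the sequence.  Low-complexity
    k-mers (fewer than three distinct bases, e.g. homopolymer runs) and
    k-mers containing N are masked out.  Returns (window start positions,
    z-scores against the sequence-wide mean).
    """
    if not (6 <= k <= 16):
        raise ValueError("k must be in [6, 16]")
    seq = seq.upper()
    n = len(seq)
    if n < window:
        raise ValueError("window larger than sequence")
    counts: dict[str, int] = {}
    kmers: list[Optional[str]] = []
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer or len(set(kmer)) < 3:
            kmers.append(None)
            continue
        canon = min(kmer, revcomp(kmer))
        kmers.append(canon)
        counts[canon] = counts.get(canon, 0) + 1
    repeated = np.array(
        [1 if km is not None and counts[km] >= 2 else 0 for km in kmers],
        dtype=np.int32,
    )
    cum = np.concatenate([[0], np.cumsum(repeated)])
    starts = np.arange(0, n - window + 1, window)
    dens = np.array(
        [cum[min(s + window, len(repeated))] - cum[s] for s in starts], dtype=float
    )
    mu = dens.mean()
    sd = dens.std()
    z = (dens - mu) / sd if sd > 0 else np.zeros_like(dens)
    return starts, z


def repeat_ori_candidate(seq: str, k: int = DEFAULT_K, window: int = DEFAULT_WINDOW,
                         z_threshold: float = DEFAULT_Z_THRESHOLD) -> Optional[OriPrediction]:
    starts, z = repeat_density_profile(seq, k, window)
    if len(z) == 0:
        return None
    idx = int(np.argmax(z))
    if z[idx] < z_threshold:
        return None
    return OriPrediction("repeat", int(starts[idx]),
                         int(min(starts[idx] + window, len(seq))), float(z[idx]))


def call_ori(skew_pred: Optional[OriPrediction],
             repeat_pred: Optional[OriPrediction],
             agree_distance: int = DEFAULT_AGREE_DISTANCE) -> list[OriPrediction]:
    """Combine the two predictors into 0, 1 or 2 origin calls.

    Both within ``agree_distance`` -> one merged origin; both successful but
    distant -> two origins; one successful -> that one; none -> empty list
    ("not found").
    """
    preds = [p for p in (skew_pred, repeat_pred) if p is not None]
    if len(preds) < 2:
        return preds
    if abs(skew_pred.midpoint - repeat_pred.midpoint) <= agree_distance:
        return [
            OriPrediction(
                "skew+repeat",
                min(skew_pred.start, repeat_pred.start),
                max(skew_pred.end, repeat_pred.end),
                max(skew_pred.statistic, repeat_pred.statistic),
            )
        ]
    return preds


def load_rep_references() -> list[tuple[str, str, str]]:
    """Load the packaged synthetic Rep exemplars: (id, class, sequence).

    The exemplars are synthetic stand-ins generated once and frozen; the
    class labels (MCM, MCM-like, t26-22p-like) are carried in the FASTA
    headers.
    """
    path = _data_path("rep_references_synthetic.faa")
    refs = []
    with open(path) as fh:
        name = cls = None
        chunks: list[str] = []
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    refs.append((name, cls, "".join(chunks)))
                fields = line[1:].split()
                name = fields[0]
                cls = dict(f.split("=") for f in fields[1:] if "=" in f)["class"]
                chunks = []
            elif line:
                chunks.append(line)
        if name is not None:
            refs.append((name, cls, "".join(chunks)))
    if not refs:
        raise ValueError("empty Rep reference set")
    return refs


def classify_rep_protein(protein: str,
                         reference_set: Optional[list[tuple[str, str, str]]] = None,
                         threshold_pct: float = DEFAULT_BDBH_THRESHOLD) -> Optional[str]:
    """Label a protein by its best reference hit above the orthology
    threshold; None when nothing scores high enough."""
    if reference_set is None:
        reference_set = load_rep_references()
    if not reference_set:
        raise ValueError("empty Rep reference set")
    if not protein:
        raise ValueError("empty protein")
    best_cls, best_norm = None, 0.0
    for _rid, cls, rseq in sorted(reference_set):
        s = raw_score(protein, rseq)
        norm = 100.0 * s / self_score(protein)
        if norm > best_norm:
            best_cls, best_norm = cls, norm
    return best_cls if best_norm > threshold_pct else None
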