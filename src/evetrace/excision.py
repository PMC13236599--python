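"""Long-read signatures of proviral activation.

Against the integrated reference, three signatures identify an activated
element: reads spanning the re-formed attP junction (excision and
circularization), fold-back reads that map sense then antisense around an
exact internal site (hairpin telomeres formed at the palindromic telRL site),
and coverage enrichment over the element (replication).  The detector reports
the fold-back signature, not its molecular origin: covalently closed
telomeres and replication intermediates are indistinguishable here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import junctions
from .attsites import RepeatHit, find_inverted_repeats, max_even_palindrome
from .util import SeqRecord, revcomp


@dataclass
class SpanEvent:
    """A read whose anchor chain jumps from the EVE right terminus to the left
    terminus: the signature of the excised circle's attP junction."""

    read_id: str
    read_offset: int  # read coordinate of the junction
    right_coord: int  # reference coordinate near the EVE right end
    left_coord: int  # reference coordinate near the EVE left end


@dataclass
class FoldbackEvent:
    read_id: str
    reversion_coord: float  # reference coordinate where orientation flips
    left_arm_len: int
    right_arm_len: int
    strand_order: str  # '+-' or '-+'


@dataclass
class ReversionCluster:
    consensus_coord: float
    support: int
    spread: float
    secondary: list[tuple[float, int]] = field(default_factory=list)


@dataclass
class TelomereSite:
    core_start: int
    core_end: int
    core_seq: str
    apex_coord: float  # centre of the palindromic core
    outer_repeats: list[RepeatHit] = field(default_factory=list)

    @property
    def palindrome_len(self) -> int:
        return self.core_end - self.core_start


@dataclass
class ExcisionReport:
    n_span: int
    n_foldback: int
    telrl_coord: float | None
    palindrome_len: int
    coverage_ratio: float | None
    circularization: bool
    linearization: bool
    replication: bool


# ---------------------------------------------------------------------------


def detect_attP_spanning(
    reads: Sequence[SeqRecord],
    integrated_ref: SeqRecord,
    eve_interval: tuple[int, int],
    tol: int = 50,
    terminus_window: int = 500,
    k: int = 15,
    min_anchor: int = 50,
) -> list[SpanEvent]:
    """Reads whose colinear chain jumps right-terminus -> left-terminus.

    Both read orientations are tried; adjacent plus-strand anchors with a read
    gap within +-tol qualify when the first ends within terminus_window of the
    EVE right end and the second starts within terminus_window of the left end.
    """
    i0, i1 = eve_interval
    events = []
    for read in reads:
        ev = None
        for seq in (read.seq, revcomp(read.seq)):
            anchors = sorted(
                (a for a in junctions.find_anchors(seq, integrated_ref.seq, k)
                 if a.strand == "+" and a.length >= min_anchor),
                key=lambda a: a.q_start,
            )
            for a, b in zip(anchors, anchors[1:]):
                if (
                    abs(b.q_start - a.q_end) <= tol
                    and abs(a.r_end - i1) <= terminus_window
                    and abs(b.r_start - i0) <= terminus_window
                ):
                    ev = SpanEvent(read.id, a.q_end, a.r_end, b.r_start)
                    break
            if ev:
                break
        if ev:
            events.append(ev)
    return events


def detect_foldback(
    reads: Sequence[SeqRecord],
    ref: SeqRecord,
    min_arm: int = 100,
    k: int = 15,
    min_overlap_frac: float = 0.5,
    max_q_overlap: int = 50,
) -> list[FoldbackEvent]:
    """Reads mapping sense then antisense over overlapping reference intervals.

    The two arms must overlap on the reference by at least min_overlap_frac of
    the shorter arm (chimeras joining distant loci are excluded).  The
    reversion coordinate is the midpoint between the innermost anchor edges:
    the two reference end coordinates for a '+-' read, the two start
    coordinates for a '-+' read.
    """
    events = []
    for read in reads:
        anchors = junctions.find_anchors(read.seq, ref.seq, k)
        plus = [a for a in anchors if a.strand == "+" and a.length >= min_arm]
        minus = [a for a in anchors if a.strand == "-" and a.length >= min_arm]
        if not plus or not minus:
            continue
        p = max(plus, key=lambda a: a.length)
        m = max(minus, key=lambda a: a.length)
        q_overlap = min(p.q_end, m.q_end) - max(p.q_start, m.q_start)
        if q_overlap > max_q_overlap:
            continue
        r_overlap = min(p.r_end, m.r_end) - max(p.r_start, m.r_start)
        if r_overlap < min_overlap_frac * min(p.length, m.length):
            continue
        order = "+-" if p.q_start <= m.q_start else "-+"
        if q_overlap > 0:
            # The arms overlap in the read by exactly the palindromic ambiguity
            # around the apex; its midpoint projected through the sense anchor
            # is the reversion coordinate.
            q_mid = (max(p.q_start, m.q_start) + min(p.q_end, m.q_end)) / 2
            rev = p.r_start + (q_mid - p.q_start)
        elif order == "+-":
            rev = (p.r_end + m.r_end) / 2
        else:
            rev = (p.r_start + m.r_start) / 2
        events.append(FoldbackEvent(read.id, rev, p.length, m.length, order))
    return events


def cluster_reversions(
    events: Sequence[FoldbackEvent], radius: int = 20
) -> ReversionCluster:
    """Single-linkage clustering of reversion coordinates at `radius`.

    Returns the largest cluster's median coordinate, support and spread;
    smaller clusters are listed as (median, support) secondaries.
    """
    if not events:
        raise ValueError("no fold-back events to cluster")
    coords = np.sort(np.array([e.reversion_coord for e in events]))
    breaks = np.nonzero(np.diff(coords) > radius)[0]
    clusters = np.split(coords, breaks + 1)
    clusters.sort(key=lambda c: (-len(c), c[0]))
    top = clusters[0]
    return ReversionCluster(
        consensus_coord=float(np.median(top)),
        support=len(top),
        spread=float(top.max() - top.min()),
        secondary=[(float(np.median(c)), len(c)) for c in clusters[1:]],
    )


def locate_telrl(
    consensus_coord: float,
    ref: SeqRecord,
    window: int = 50,
    core_min: int = 4,
    core_max: int = 12,
) -> TelomereSite | None:
    """Find the palindromic telRL core nearest the fold-back consensus.

    Every boundary within +-window is tested for a maximal even palindrome of
    length in [core_min, core_max]; the centre nearest consensus_coord wins,
    ties broken leftmost.  The surrounding inverted repeat is annotated.
    Returns None when no qualifying palindrome exists (the linearization flag
    is then withheld by the caller).
    """
    if window < core_max:
        raise ValueError("window must be >= core_max")
    centre = int(round(consensus_coord))
    best = None
    for j in range(max(1, centre - window), min(len(ref.seq), centre + window + 1)):
        plen = max_even_palindrome(ref.seq, j, core_max)
        if plen >= core_min:
            key = (abs(j - consensus_coord), j)
            if best is None or key < best[0]:
                best = (key, j, plen)
    if best is None:
        return None
    _, j, plen = best
    lo = max(0, j - plen // 2 - 40)
    hi = min(len(ref.seq), j + plen // 2 + 40)
    outer = [
        r
        for r in find_inverted_repeats(ref.seq[lo:hi], min_arm=5, max_loop=2 * plen + 10)
        if r.arm_len > plen // 2
    ]
    return TelomereSite(j - plen // 2, j + plen // 2, ref.seq[j - plen // 2 : j + plen // 2],
                        float(j), outer)


def coverage_ratio(
    reads: Sequence[SeqRecord],
    ref: SeqRecord,
    eve_interval: tuple[int, int],
    k: int = 15,
    min_anchor: int = 50,
) -> float | None:
    """Median anchor-chain depth inside the EVE over median depth outside.

    Both arms of a fold-back read contribute; depth is accumulated over the
    reference intervals of every anchor >= min_anchor.  Undefined (None, with
    a warning) when the host median depth is zero.
    """
    n = len(ref.seq)
    diff = np.zeros(n + 1)
    for read in reads:
        for a in junctions.find_anchors(read.seq, ref.seq, k):
            if a.length >= min_anchor:
                diff[a.r_start] += 1
                diff[a.r_end] -= 1
    depth = np.cumsum(diff[:-1])
    i0, i1 = eve_interval
    inside = np.median(depth[i0:i1])
    outside_mask = np.ones(n, dtype=bool)
    outside_mask[i0:i1] = False
    outside = np.median(depth[outside_mask])
    if outside == 0:
        warnings.warn("zero host coverage; ratio undefined", stacklevel=2)
        return None
    return float(inside / outside)


def summarize(
    span: Sequence[SpanEvent],
    foldback: ReversionCluster | None,
    telsite: TelomereSite | None,
    cov: float | None,
    min_span: int = 3,
    min_fb: int = 3,
    min_ratio: float = 2.0,
) -> ExcisionReport:
    """Combine the three signatures into verdict flags."""
    n_fb = foldback.support if foldback is not None else 0
    return ExcisionReport(
        n_span=len(span),
        n_foldback=n_fb,
        telrl_coord=telsite.apex_coord if telsite else None,
        palindrome_len=telsite.palindrome_len if telsite else 0,
        coverage_ratio=cov,
        circularization=len(span) >= min_span,
        linearization=telsite is not None and n_fb >= min_fb,
        replication=cov is not None and cov >= min_ratio,
    )
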