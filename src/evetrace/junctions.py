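"""Exact insertion-junction resolution and integration-mechanism classification.

The EVE-bearing haplotype is compared with the EVE-free homolog through
maximal-exact-match anchors chained colinearly (the package's internal
replacement for an external mapper).  An insertion appears as a pair of
flanking anchors whose query gap exceeds their reference gap; microhomology
shared between host and virus at the junction makes the exact breakpoint
ambiguous over a short window (ambiguity_shift), and the canonical breakpoint
is reported leftmost on the host forward strand.

Mechanism calls:
  recombinase_core — a short string (the attB/attP core, 'CC' in the elements
    modelled here) terminates the host left flank and the viral right end;
    tyrosine-recombinase-style integration on minimal homology.
  dde_tsd — the host bases at the target are duplicated on both sides of the
    inserted element (>= 4 nt), the DDE/D-transposase signature.
  unclassified — neither signature (blunt junction).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from functools import lru_cache

from .util import SeqRecord, common_suffix_len, revcomp


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match: query/reference start (forward coords), length, strand."""

    q_start: int
    r_start: int
    length: int
    strand: str = "+"

    @property
    def q_end(self) -> int:
        return self.q_start + self.length

    @property
    def r_end(self) -> int:
        return self.r_start + self.length


@dataclass
class AnchorChain:
    query_id: str
    ref_id: str
    anchors: list[Anchor]          # best colinear chain
    all_anchors: list[Anchor]      # every maximal exact match >= k
    score: int = 0                 # summed anchor length of the chain
    strand: str = "+"


@dataclass
class JunctionRecord:
    chrom: str
    insert_start: int              # canonical leftmost, on the bearing haplotype
    insert_end: int
    core: str = ""
    core_len: int = 0
    tsd: str | None = None
    tsd_len: int = 0
    mechanism: str = "unclassified"
    ambiguity_shift: int = 0       # bp over which the breakpoint can slide
    orientation: str = "+"
    free_pos: int = 0              # leftmost breakpoint on the EVE-free homolog
    flagged: bool = False
    note: str = ""

    @property
    def insert_len(self) -> int:
        return self.insert_end - self.insert_start


@dataclass
class AttQuartet:
    attB: str
    attP: str
    attL: str
    attR: str
    core: str
    flank_w: int


# ---------------------------------------------------------------------------
# anchors


def find_anchors(query: str, reference: str, k: int = 15) -> list[Anchor]:
    """All maximal exact matches of length >= k, on both strands."""
    if k < 11:
        raise ValueError("k must be >= 11")
    return list(_find_anchors_cached(query, reference, k))


@lru_cache(maxsize=65536)
def _find_anchors_cached(query: str, reference: str, k: int) -> tuple[Anchor, ...]:
    out = []
    out.extend(_mems_plus(query, reference, k, "+"))
    rc = _revcomp_cached(reference)
    for a in _mems_plus(query, rc, k, "-"):
        # convert match coordinates on the reverse complement back to forward
        out.append(Anchor(a.q_start, len(reference) - a.r_start - a.length, a.length, "-"))
    return tuple(out)


@lru_cache(maxsize=8)
def _revcomp_cached(seq: str) -> str:
    return revcomp(seq)


@lru_cache(maxsize=8)
def _kmer_index(reference: str, k: int) -> dict[str, list[int]]:
    """Reference k-mer index, cached so read sets reuse it across calls."""
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(reference) - k + 1):
        index[reference[j : j + k]].append(j)
    index.default_factory = None
    return index


def _mems_plus(query: str, reference: str, k: int, strand: str) -> list[Anchor]:
    index = _kmer_index(reference, k)
    seen = set()
    out = []
    for i in range(len(query) - k + 1):
        for j in index.get(query[i : i + k], ()):
            if i > 0 and j > 0 and query[i - 1] == reference[j - 1]:
                continue  # not left-maximal; counted at its true start
            if (i, j) in seen:
                continue
            L = k
            qn, rn = len(query), len(reference)
            while i + L < qn and j + L < rn and query[i + L] == reference[j + L]:
                L += 1
            seen.add((i, j))
            out.append(Anchor(i, j, L, strand))
    return out


def chain_anchors(anchors: list[Anchor], max_ref_overlap: int = 100) -> tuple[list[Anchor], int]:
    """Highest-scoring colinear chain (score = summed anchor length).

    Anchors must ascend in both coordinates; overlap up to max_ref_overlap is
    tolerated on either axis so that junction microhomology (shared core /
    target-site duplication / chance flank identity) does not break the
    flanking chain.  Deterministic.
    """
    if not anchors:
        return [], 0
    best_chain: list[Anchor] = []
    best_score = 0
    for strand in ("+", "-"):
        sub = sorted(
            (a for a in anchors if a.strand == strand), key=lambda a: (a.q_start, a.r_start)
        )
        if not sub:
            continue
        n = len(sub)
        score = [a.length for a in sub]
        prev = [-1] * n
        for i in range(n):
            ai = sub[i]
            for j in range(i):
                aj = sub[j]
                if aj.q_start >= ai.q_start or aj.q_end > ai.q_start + max_ref_overlap:
                    continue
                if strand == "+":
                    ok = aj.r_start < ai.r_start and aj.r_end <= ai.r_start + max_ref_overlap
                else:
                    ok = aj.r_start > ai.r_start and ai.r_end <= aj.r_start + max_ref_overlap
                if ok and score[j] + ai.length > score[i]:
                    score[i] = score[j] + ai.length
                    prev[i] = j
        i = max(range(n), key=lambda i: (score[i], -sub[i].q_start))
        if score[i] > best_score:
            chain = []
            while i != -1:
                chain.append(sub[i])
                i = prev[i]
            best_chain = chain[::-1]
            best_score = sum(a.length for a in best_chain)
    return best_chain, best_score


def anchor_map(query: SeqRecord, reference: SeqRecord, k: int = 15) -> AnchorChain:
    """Anchor a query against a reference and keep the best colinear chain."""
    if not query.seq or not reference.seq:
        raise ValueError("sequences must be non-empty")
    anchors = find_anchors(query.seq, reference.seq, k)
    chain, score = chain_anchors(anchors)
    strand = chain[0].strand if chain else "+"
    return AnchorChain(query.id, reference.id, chain, anchors, score, strand)


# ---------------------------------------------------------------------------
# insertion resolution


def resolve_insertion(
    bearing: SeqRecord,
    free: SeqRecord,
    k: int = 15,
    min_insert: int = 50,
    min_flank: int = 30,
) -> list[JunctionRecord]:
    """Locate inserted segments on the bearing haplotype relative to the free one.

    Walks adjacent anchors of the best chain; a pair whose query gap exceeds
    its reference gap by at least min_insert defines an insertion.  The
    breakpoint is canonicalized leftmost within the microhomology window.
    Returns one record per insertion ([] when the haplotypes are identical);
    multiple insertions are returned together, flagged.
    """
    chain = anchor_map(bearing, free, k).anchors
    records = []
    for a, b in zip(chain, chain[1:]):
        if a.length < min_flank or b.length < min_flank:
            continue
        gap_q = b.q_start - a.q_end
        gap_r = b.r_start - a.r_end
        net = gap_q - gap_r
        if net < min_insert:
            continue
        m = max(0, a.r_end - b.r_start)  # flank microhomology (slide window)
        start = a.q_end - m
        records.append(
            JunctionRecord(
                chrom=bearing.id,
                insert_start=start,
                insert_end=start + net,
                ambiguity_shift=m,
                free_pos=b.r_start,
            )
        )
    if len(records) > 1:
        for r in records:
            r.flagged = True
            r.note = f"{len(records)} insertions on {bearing.id}"
    return records


def classify_mechanism(
    rec: JunctionRecord,
    bearing: SeqRecord,
    free: SeqRecord,
    eve_left_end: str = "",
    eve_right_end: str = "",
    tsd_min: int = 4,
    tsd_max: int = 30,
    core_max: int = 10,
) -> JunctionRecord:
    """Assign recombinase_core / dde_tsd / unclassified to a resolved insertion.

    From the two haplotypes alone, an m-bp target-site duplication and m bp of
    junction microhomology are the same observable: the flanking-anchor
    overlap.  They are told apart by magnitude and by identity with the
    conserved viral terminus:

    * recombinase_core — the viral right end locates the junction and a
      shared string (1..core_max nt) terminates both the host left flank and
      the viral end there; the signature of site-specific recombination on
      minimal homology.  Without viral ends a short overlap (< tsd_min) is
      reported as the core.
    * dde_tsd — the overlap is >= tsd_min (default 4) and is NOT explained by
      the viral terminus: the host target sequence flanks the element on both
      sides, the DDE/D-transposase duplication signature.  tsd_min keeps a
      2-bp core from ever being miscalled as a duplication.
    """
    bq, fq = bearing.seq, free.seq
    L = rec.insert_len
    m = rec.ambiguity_shift

    junction = _locate_right_junction(rec, bq, eve_left_end, eve_right_end)
    c = 0
    if junction is not None:
        j, orientation = junction
        c = common_suffix_len(fq[: j - L], bq[:j], cap=core_max)
        if c >= 1:
            rec.orientation = orientation
            rec.mechanism = "recombinase_core"
            rec.core = bq[j - c : j]
            rec.core_len = c
            rec.tsd = None
            rec.tsd_len = 0
            return rec

    if tsd_min <= m:
        t = min(m, tsd_max)
        ra1 = rec.free_pos + m  # left-flank anchor end on the free haplotype
        rec.mechanism = "dde_tsd"
        rec.tsd = fq[ra1 - t : ra1]
        rec.tsd_len = t
        rec.core = ""
        rec.core_len = 0
        return rec

    if junction is None and 1 <= m:
        # no viral ends to anchor the junction: report the overlap as the core
        rec.mechanism = "recombinase_core"
        rec.core = fq[rec.free_pos + m - min(m, core_max) : rec.free_pos + m]
        rec.core_len = len(rec.core)
        rec.tsd = None
        rec.tsd_len = 0
        return rec

    rec.mechanism = "unclassified"
    rec.core = ""
    rec.core_len = 0
    rec.tsd = None
    rec.tsd_len = 0
    return rec


def _locate_right_junction(
    rec: JunctionRecord, bq: str, eve_left_end: str, eve_right_end: str
) -> tuple[int, str] | None:
    """Find where the viral right terminus ends in the bearing haplotype.

    Tries the forward orientation (right end as given) then a reverse-strand
    integration (revcomp of the left end plays the right terminus).
    """
    lo = rec.insert_start
    hi = rec.insert_end + rec.ambiguity_shift
    for end_seq, orientation in ((eve_right_end, "+"), (revcomp(eve_left_end), "-")):
        if not end_seq:
            continue
        pos = bq.find(end_seq, lo, hi)
        if pos != -1:
            return pos + len(end_seq), orientation
    return None


def extract_att_quartet(
    rec: JunctionRecord,
    bearing: SeqRecord,
    free: SeqRecord,
    flank_w: int = 30,
    eve_left_end: str = "",
    eve_right_end: str = "",
) -> AttQuartet:
    """Cut attB/attL/attR and reconstruct attP around a recombinase junction.

    attB comes from the free haplotype centred on the core; attL/attR from the
    two junctions of the bearing haplotype; attP joins the insert's right
    terminus (which carries the single core copy) to its left terminus, i.e.
    the junction sequence of the excised circle.
    """
    if rec.mechanism != "recombinase_core":
        raise ValueError("att quartet is defined only for recombinase_core junctions")
    bq, fq = bearing.seq, free.seq
    L = rec.insert_len
    junction = _locate_right_junction(rec, bq, eve_left_end, eve_right_end)
    if junction is not None:
        j = junction[0]
    else:
        j = rec.insert_end + rec.ambiguity_shift  # rightmost placement
    f0 = j - L  # host breakpoint: host core copy ends here on both haplotypes
    w = flank_w
    attL = bq[f0 - w : f0 + w]
    attR = bq[j - w : j + w]
    attB = fq[f0 - w : f0 + w]
    attP = bq[j - w : j] + bq[f0 : f0 + w]
    quartet = AttQuartet(attB, attP, attL, attR, rec.core, w)
    _check_quartet(quartet)
    return quartet


def _check_quartet(q: AttQuartet) -> None:
    for name, site in (("attB", q.attB), ("attP", q.attP), ("attL", q.attL), ("attR", q.attR)):
        if q.core and q.core not in site:
            raise ValueError(f"core {q.core!r} missing from {name}")
    if not (q.attL[: q.flank_w] == q.attB[: q.flank_w]
            and q.attR[-q.flank_w :] == q.attB[-q.flank_w :]):
        raise ValueError("attL/attR host halves do not match attB")
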