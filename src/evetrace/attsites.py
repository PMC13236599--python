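"""Terminus profiles, genome scanning, filtering and attB/attP consensus.

EVE left/right terminal sequences are summarised as ungapped position
log-odds profiles (counts with a pseudocount against a background
composition), scanned over both strands of target contigs, filtered with the
screen's retention rules (hits of at least 80 bp that reach within 50 bp of
the model's terminal end), and deduplicated on identical flanking host
sequence.  Sequence logos are frequency/information-content matrices;
rendering is a thin optional layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .util import BASES, SeqRecord, encode, revcomp


@dataclass
class TerminusProfile:
    """Ungapped position log-odds model of one EVE end.

    log-odds[b, j] = log2( ((count[b, j] + alpha) / (n + 4 alpha)) / bg[b] ).
    The terminal column is column 0 for a left-end model and column L-1 for a
    right-end model (the column that abuts the host junction).
    """

    side: str  # left | right
    counts: np.ndarray  # 4 x L
    alpha: float = 1.0
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    n_seqs: int = 0

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        tot = self.counts.sum(axis=0, keepdims=True)
        return (self.counts + self.alpha) / (tot + 4 * self.alpha)

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):  # -inf is correct for alpha == 0
            return np.log2(self.frequencies / self.background[:, None])

    @property
    def terminal_column(self) -> int:
        return 0 if self.side == "left" else self.length - 1

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.log_odds.T, columns=list(BASES))


@dataclass
class TerminusHit:
    contig: str
    start: int
    end: int
    strand: str
    score: float
    hit_len: int
    dist_to_model_end: int
    model_start: int = 0  # model columns covered: [model_start, model_end)
    model_end: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start != self.hit_len:
            raise ValueError("hit_len must equal end - start")


@dataclass
class LogoMatrix:
    """Per-position base frequencies and information content (bits)."""

    frequencies: pd.DataFrame  # L x 4, columns ACGT
    information: np.ndarray  # IC_j = 2 - H_j


@dataclass
class RepeatHit:
    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    kind: str  # inverted | direct
    arm_len: int
    loop_len: int
    mismatches: int
    at_fraction: float


# ---------------------------------------------------------------------------
# alignment trimming and profile construction


def trim_alignment(
    aligned_seqs: Sequence[str], occupancy_min: float = 0.5, ic_min: float = 0.0
) -> list[str]:
    """Keep the maximal terminal-anchored run of well-conserved columns.

    A column qualifies when its non-gap occupancy is >= occupancy_min and its
    information content (computed over non-gap bases) is >= ic_min.  The
    longest qualifying run anchored at either end of the alignment is kept.
    """
    if not aligned_seqs:
        raise ValueError("empty alignment")
    if len({len(s) for s in aligned_seqs}) != 1:
        raise ValueError("aligned rows must have equal length")
    if len(aligned_seqs) == 1:
        warnings.warn("single-row alignment returned unchanged", stacklevel=2)
        return list(aligned_seqs)
    L = len(aligned_seqs[0])
    n = len(aligned_seqs)
    ok = np.zeros(L, dtype=bool)
    for j in range(L):
        col = [s[j] for s in aligned_seqs]
        bases = [b for b in col if b != "-"]
        occ = len(bases) / n
        if occ < occupancy_min or not bases:
            continue
        freqs = np.array([bases.count(b) for b in BASES], dtype=float)
        p = freqs[freqs > 0] / len(bases)
        ic = 2.0 + float((p * np.log2(p)).sum())
        ok[j] = ic >= ic_min
    left_run = int(np.argmin(ok)) if not ok.all() else L
    right_run = int(np.argmin(ok[::-1])) if not ok.all() else L
    if left_run >= right_run:
        lo, hi = 0, left_run
    else:
        lo, hi = L - right_run, L
    return [s[lo:hi] for s in aligned_seqs]


def build_profile(
    seqs: Sequence[str],
    side: str,
    alpha: float = 1.0,
    background: Sequence[float] | None = None,
) -> TerminusProfile:
    """Count matrix, frequencies and log-odds from equal-length ungapped seqs."""
    if not seqs:
        raise ValueError("no sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must have equal length")
    L = len(seqs[0])
    counts = np.zeros((4, L))
    idx = {b: i for i, b in enumerate(BASES)}
    for s in seqs:
        for j, b in enumerate(s):
            counts[idx[b], j] += 1
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    return TerminusProfile(side=side, counts=counts, alpha=alpha, background=bg,
                           n_seqs=len(seqs))


# ---------------------------------------------------------------------------
# scanning


def scan_genome(
    profile: TerminusProfile,
    contigs: Sequence[SeqRecord],
    score_min: float | None = None,
    allow_partial: bool = True,
    min_partial: int = 20,
) -> list[TerminusHit]:
    """Slide the profile over both strands of every contig.

    Full-length windows everywhere; with allow_partial, truncated model
    prefix/suffix windows at contig edges (at least min_partial columns).
    Non-overlapping hits above score_min are reported, greedily by score.
    score_min defaults to 0.6 x the maximum achievable profile score.
    """
    if score_min is None:
        score_min = 0.6 * profile.max_score
    M = profile.log_odds
    L = profile.length
    out: list[TerminusHit] = []
    for contig in contigs:
        candidates: list[tuple[float, int, int, str, int, int]] = []
        for strand in ("+", "-"):
            seq = contig.seq if strand == "+" else revcomp(contig.seq)
            n = len(seq)
            if n >= L:
                enc = encode(seq)
                scores = np.zeros(n - L + 1)
                for j in range(L):
                    scores += M[:, j][enc[j : j + n - L + 1]]
                for i in np.nonzero(scores >= score_min)[0]:
                    candidates.append((float(scores[i]), int(i), int(i) + L, strand, 0, L))
            if allow_partial:
                enc = encode(seq)
                for t in range(min_partial, min(L, n + 1)):
                    if t == L:
                        continue
                    # model suffix of length t at contig start (terminal columns
                    # beyond the contig edge are missing)
                    s = float(M[enc[:t], np.arange(L - t, L)].sum())
                    if s >= score_min:
                        candidates.append((s, 0, t, strand, L - t, L))
                    # model prefix of length t at contig end
                    s = float(M[enc[n - t :], np.arange(t)].sum())
                    if s >= score_min:
                        candidates.append((s, n - t, n, strand, 0, t))
        out.extend(_select_hits(candidates, contig, profile))
    return out


def _select_hits(candidates, contig: SeqRecord, profile: TerminusProfile) -> list[TerminusHit]:
    taken: list[tuple[int, int]] = []
    hits = []
    n = len(contig.seq)
    T = profile.terminal_column
    for score, start, end, strand, m0, m1 in sorted(
        candidates, key=lambda c: (-c[0], c[1], c[3])
    ):
        if strand == "-":
            start, end = n - end, n - start
        if any(start < e and s < end for s, e in taken):
            continue
        taken.append((start, end))
        dist = 0 if m0 <= T < m1 else (m0 - T if T < m0 else T - (m1 - 1))
        hits.append(
            TerminusHit(contig.id, start, end, strand, score, end - start, dist, m0, m1)
        )
    hits.sort(key=lambda h: (h.contig, h.start))
    return hits


def filter_hits(
    hits: Sequence[TerminusHit], min_len: int = 80, max_dist: int = 50
) -> list[TerminusHit]:
    """Retain hits of at least min_len bp reaching within max_dist of the
    model's terminal end (both bounds inclusive); order-preserving, idempotent."""
    return [h for h in hits if h.hit_len >= min_len and h.dist_to_model_end <= max_dist]


def dedup_flanks(
    hits: Sequence[TerminusHit],
    contigs: Sequence[SeqRecord],
    side: str,
    flank_w: int = 100,
) -> list[TerminusHit]:
    """Collapse hits whose flanking host sequence is string-identical.

    The flank is upstream of the terminus for left ends and downstream for
    right ends, read in the hit's orientation; a flank running off the contig
    edge is truncated and compared as-is.  The first hit by (contig, start)
    represents each group.
    """
    if flank_w <= 0:
        raise ValueError("flank_w must be positive")
    seqs = {c.id: c.seq for c in contigs}
    seen: dict[str, TerminusHit] = {}
    out = []
    for h in sorted(hits, key=lambda h: (h.contig, h.start)):
        seq = seqs[h.contig]
        outward_left = (side == "left") == (h.strand == "+")
        if outward_left:
            flank = seq[max(0, h.start - flank_w) : h.start]
            if h.strand == "-":
                flank = revcomp(flank)
        else:
            flank = seq[h.end : h.end + flank_w]
            if h.strand == "-":
                flank = revcomp(flank)
        if flank not in seen:
            seen[flank] = h
            out.append(h)
    return out


# ---------------------------------------------------------------------------
# logos and consensus


def make_logo(seqs: Sequence[str]) -> LogoMatrix:
    """Column frequencies and information content IC_j = 2 - H_j (no
    small-sample correction)."""
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must have equal length")
    L = len(seqs[0])
    idx = {b: i for i, b in enumerate(BASES)}
    counts = np.zeros((L, 4))
    for s in seqs:
        for j, b in enumerate(s):
            counts[j, idx[b]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    return LogoMatrix(pd.DataFrame(freqs, columns=list(BASES)), ic)


def render_logo(logo: LogoMatrix, path: str) -> None:
    """Optional image rendering of a LogoMatrix (stacked letter heights)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    L = len(logo.information)
    fig, ax = plt.subplots(figsize=(max(4, L / 4), 2.5))
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    for j in range(L):
        heights = logo.frequencies.iloc[j] * logo.information[j]
        y = 0.0
        for b in heights.sort_values().index:
            h = heights[b]
            if h <= 0:
                continue
            ax.text(j + 0.5, y + h / 2, b, ha="center", va="center",
                    fontsize=10, color=colors[b])
            y += h
    ax.set_xlim(0, L)
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def _consensus(seqs: Sequence[str]) -> str:
    if not seqs:
        return ""
    L = min(len(s) for s in seqs)
    out = []
    for j in range(L):
        col = [s[len(s) - L + j] if len(s) != L else s[j] for s in seqs]
        out.append(max(BASES, key=col.count))
    return "".join(out)


def infer_att_consensus(
    attL_seqs: Sequence[str],
    attR_seqs: Sequence[str],
    junction_l: int | None = None,
    junction_r: int | None = None,
    core_guess: str | None = None,
    max_core: int = 12,
) -> tuple[str, str, str]:
    """Reconstruct attB/attP consensus and the recombination core.

    attL sequences are host-flank + viral-left-terminus, attR sequences
    viral-right-terminus + host-flank, each aligned on its junction (given as
    a column index; defaults to the midpoint).  The core is the maximal run of
    columns ending at the junction where the attL host-side consensus agrees
    with the viral right-terminus consensus — the string shared by host attB
    and viral attP.  attB re-joins the two host flanks across one core copy;
    attP re-joins the two viral termini.
    """
    jl = junction_l if junction_l is not None else len(attL_seqs[0]) // 2
    jr = junction_r if junction_r is not None else len(attR_seqs[0]) // 2
    attL_host = _consensus([s[:jl] for s in attL_seqs])
    attL_viral = _consensus([s[jl:] for s in attL_seqs])
    attR_viral = _consensus([s[:jr] for s in attR_seqs])
    attR_host = _consensus([s[jr:] for s in attR_seqs])
    k = 0
    while (
        k < min(len(attL_host), len(attR_viral), max_core)
        and attL_host[-1 - k] == attR_viral[-1 - k]
    ):
        k += 1
    core = attL_host[len(attL_host) - k :] if k else ""
    if not core:
        warnings.warn("junction columns disagree; core length 0", stacklevel=2)
        if core_guess:
            core = ""
    attB = attL_host + attR_host
    attP = attR_viral + attL_viral
    return attB, attP, core


# ---------------------------------------------------------------------------
# repeats


def find_inverted_repeats(
    seq: str,
    min_arm: int = 4,
    max_loop: int = 20,
    max_mismatch: int = 0,
    kind: str = "inverted",
) -> list[RepeatHit]:
    """Enumerate maximal inverted (or direct) repeats.

    Inverted: left arm [i-a, i), loop [i, j), right arm [j, j+a) with the
    right arm reverse-complement-matching the left within max_mismatch;
    perfect palindromes are the loop-0 special case.  Direct: two copies
    separated by a gap <= max_loop.  Arms are maximal; redundant hits nested
    inside a longer hit with the same centre are dropped.
    """
    if min_arm <= 0 or max_loop < 0:
        raise ValueError("parameters must be positive")
    n = len(seq)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    hits: list[RepeatHit] = []
    if kind == "inverted":
        for loop in range(max_loop + 1):
            for i in range(n):  # left arm ends at i, right arm starts at i+loop
                j = i + loop
                a = 0
                mm = 0
                best = None
                while i - a - 1 >= 0 and j + a < n:
                    if comp[seq[i - a - 1]] != seq[j + a]:
                        mm += 1
                        if mm > max_mismatch:
                            break
                    a += 1
                    best = (a, mm)
                if best and best[0] >= min_arm:
                    a, mm = best
                    arms = seq[i - a : i] + seq[j : j + a]
                    hits.append(
                        RepeatHit((i - a, i), (j, j + a), "inverted", a, loop, mm,
                                  (arms.count("A") + arms.count("T")) / len(arms))
                    )
    elif kind == "direct":
        for d in range(min_arm, n):  # offset between copies
            for p in range(n - d):
                if p > 0 and seq[p - 1] == seq[p + d - 1]:
                    continue  # not left-maximal
                l = 0
                while p + l < n - d and seq[p + l] == seq[p + d + l]:
                    l += 1
                if l == 0:
                    continue
                arm = min(l, d)
                loop = d - arm
                if arm >= min_arm and loop <= max_loop:
                    arms = seq[p : p + arm] + seq[p + d : p + d + arm]
                    hits.append(
                        RepeatHit((p, p + arm), (p + d, p + d + arm), "direct",
                                  arm, loop, 0,
                                  (arms.count("A") + arms.count("T")) / len(arms))
                    )
    else:
        raise ValueError("kind must be 'inverted' or 'direct'")
    return _prune_nested(hits)


def _prune_nested(hits: list[RepeatHit]) -> list[RepeatHit]:
    hits = sorted(hits, key=lambda h: (-h.arm_len, h.left_arm))
    kept: list[RepeatHit] = []
    for h in hits:
        nested = any(
            k.left_arm[0] <= h.left_arm[0]
            and h.right_arm[1] <= k.right_arm[1]
            and k.kind == h.kind
            for k in kept
        )
        if not nested:
            kept.append(h)
    kept.sort(key=lambda h: h.left_arm)
    return kept


def max_even_palindrome(seq: str, boundary: int, cap: int) -> int:
    """Length of the maximal even palindrome centred on `boundary` (<= cap)."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    h = 0
    while (
        2 * (h + 1) <= cap
        and boundary - h - 1 >= 0
        and boundary + h < len(seq)
        and seq[boundary + h] == comp[seq[boundary - h - 1]]
    ):
        h += 1
    return 2 * h
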