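"""Synthetic genomes, EVEs, integration/excision products, long reads and crosses.

The generator emulates the architecture of latent phaeoviral endogenous viral
elements (EVEs) in brown algal genomes: hemizygous insertions at a 'CC'
dinucleotide shared between the host attB and viral attP attachment sites,
AT-rich inverted repeats flanking the core, a conserved inverted repeat at the
left terminus and imperfect direct repeats at the right terminus, an internal
palindromic telomere-resolution (telRL) site within a larger inverted repeat,
and an optional IS4-family DNA transposon that duplicates 8 nt of its target.
Real elements span 288-407 kb; the default here is scaled to 30 kb so that
every downstream stage runs at desk scale, with the real-scale numbers
reachable through the same specs.

Every operation is a pure function of its seed: identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .util import (
    SeqRecord,
    TruthSet,
    at_rich_dna,
    is_palindrome,
    random_dna,
    revcomp,
)

#: attB context planted in host genomes: weak 'ATA' extended homology followed
#: by the nearly invariant 'CC' core at which integration occurs.
ATT_B_CONTEXT = "ATACC"


@dataclass
class IrSpec:
    """An inverted repeat: arm + loop + revcomp(arm)."""

    arm_len: int = 12
    loop_len: int = 6
    at_fraction: float = 0.8


@dataclass
class DirectRepeatSpec:
    """Imperfect direct repeats near the right terminus."""

    arm_len: int = 10
    gap_len: int = 4
    mismatches: int = 1


@dataclass
class TelRlSpec:
    """The palindromic telomere-resolution site.

    The core palindrome is cleaved with a stagger (default 6 nt, the apex loop
    of the resulting hairpin) and resealed into covalently closed telL/telR
    telomeres, as in phage N15.
    """

    core_palindrome: str = "GAATTC"
    outer_ir_arm: int = 15
    position_fraction: float = 0.5
    stagger_nt: int = 6

    def __post_init__(self) -> None:
        if not is_palindrome(self.core_palindrome):
            raise ValueError("telRL core must equal its own reverse complement")
        if self.stagger_nt < 0:
            raise ValueError("stagger_nt must be >= 0")
        if not 0.0 < self.position_fraction < 1.0:
            raise ValueError("telRL position must be strictly internal")


@dataclass
class IS4Spec:
    """An IS4-family transposon that duplicates tsd_len nt of its target site."""

    length_bp: int = 2000
    tsd_len: int = 8

    def __post_init__(self) -> None:
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")


@dataclass
class EveSpec:
    """Architecture of a synthetic EVE (integrated orientation).

    length_bp defaults to a scaled 30 kb; real elements are 288,200-406,900 bp.
    gc_fraction defaults to 0.52, matching the observed 51.5-52.5% range.
    """

    length_bp: int = 30_000
    gc_fraction: float = 0.52
    attP_core: str = "CC"
    flank_ir: IrSpec = field(default_factory=lambda: IrSpec(arm_len=10, at_fraction=0.8))
    left_end_ir: IrSpec = field(default_factory=lambda: IrSpec(arm_len=12, loop_len=6))
    right_end_direct_repeats: DirectRepeatSpec = field(default_factory=DirectRepeatSpec)
    telrl: TelRlSpec = field(default_factory=TelRlSpec)
    transposon: IS4Spec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.attP_core:
            raise ValueError("attP_core must be non-empty")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must lie strictly between 0 and 1")


@dataclass
class CrossSpec:
    """A meiotic cross segregating hemizygous EVE loci.

    loci: (locus_id, chromosome_id, homolog in {0,1}). Loci on the same
    chromosome and the same homolog co-segregate; loci on the same chromosome
    but different homologs are mutually exclusive in any haploid progeny.
    """

    loci: Sequence[tuple[str, str, int]]
    active_loci: Sequence[str]
    penetrance: float = 1.0
    n_progeny: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [l[0] for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids")
        missing = set(self.active_loci) - set(ids)
        if missing:
            raise ValueError(f"active loci not declared: {sorted(missing)}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")


@dataclass
class ReadSimSpec:
    """Long-read simulation: mean depth per molecule class, length model, errors."""

    depth_per_class: Mapping[str, float] = field(
        default_factory=lambda: {
            "integrated": 5.0,
            "circle": 20.0,
            "hairpin": 20.0,
            "host_background": 5.0,
        }
    )
    read_length: tuple[float, float] = (2000.0, 200.0)
    error_rate: float = 0.0
    min_read_len: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.depth_per_class.values()):
            raise ValueError("depths must be >= 0")
        if not 0.0 <= self.error_rate <= 0.2:
            raise ValueError("error_rate must be in [0, 0.2]")


# ---------------------------------------------------------------------------
# host genomes


def make_host_genome(
    n_chrom: int,
    lengths: Sequence[int],
    gc: float = 0.52,
    seed: int = 0,
    att_context: str = ATT_B_CONTEXT,
) -> list[SeqRecord]:
    """Random host chromosomes with at least one attB context per 10 kb.

    The attB context ('ATACC' by default: the weak extended homology plus the
    'CC' core) is planted in any 10-kb block that lacks it, so integration
    sites are always available.
    """
    if len(lengths) != n_chrom:
        raise ValueError("lengths must have n_chrom entries")
    if any(n <= 0 for n in lengths):
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    chroms = []
    for c, n in enumerate(lengths):
        seq = list(random_dna(n, gc, rng))
        block = 10_000
        w = len(att_context)
        for b0 in range(0, n, block):
            b1 = min(n, b0 + block)
            if b1 - b0 < 2 * w:
                continue
            if att_context not in "".join(seq[b0:b1]):
                pos = int(rng.integers(b0 + w, b1 - w))
                seq[pos : pos + w] = att_context
        chroms.append(SeqRecord(f"chr{c + 1:02d}", "".join(seq), f"synthetic host gc={gc}"))
    return chroms


def find_attB_sites(host: SeqRecord, att_context: str = ATT_B_CONTEXT) -> list[int]:
    """Integration sites: coordinates of the base AFTER each planted core."""
    sites = []
    i = host.seq.find(att_context)
    while i != -1:
        sites.append(i + len(att_context))
        i = host.seq.find(att_context, i + 1)
    return sites


# ---------------------------------------------------------------------------
# EVEs


def _imperfect(arm: str, mismatches: int, rng: np.random.Generator) -> str:
    out = list(arm)
    if mismatches > 0:
        for pos in rng.choice(len(arm), size=min(mismatches, len(arm)), replace=False):
            others = [b for b in "ACGT" if b != out[pos]]
            out[pos] = others[int(rng.integers(3))]
    return "".join(out)


def make_eve(spec: EveSpec) -> tuple[SeqRecord, TruthSet]:
    """Build an EVE in its integrated orientation, plus its truth records.

    Layout (left to right): attP flanking-IR arm B (= revcomp of arm A),
    spacer, conserved left-end inverted repeat, ... random internal sequence
    with the telRL site at floor(position_fraction * length) ..., imperfect
    direct repeats, attP flanking-IR arm A, attP core.  The emitted sequence
    therefore ENDS with the viral copy of the core: at integration the left
    junction's core copy is contributed by the host attB and the right
    junction's by the viral attP, with no duplication beyond the shared core.

    Arm A is forced to end in 'T' so that junction homology with the planted
    host 'ATA'+core context terminates exactly at the core — the virus carries
    the core, not the weak host-side 'ATA' extension.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.length_bp
    core = spec.attP_core

    arm_a = list(at_rich_dna(spec.flank_ir.arm_len, spec.flank_ir.at_fraction, rng))
    arm_a[-1] = "T"
    arm_a = "".join(arm_a)
    arm_b = revcomp(arm_a)

    lir = spec.left_end_ir
    lir_arm = at_rich_dna(lir.arm_len, lir.at_fraction, rng)
    lir_loop = random_dna(lir.loop_len, spec.gc_fraction, rng)
    left_ir_block = lir_arm + lir_loop + revcomp(lir_arm)
    left_spacer = random_dna(5, spec.gc_fraction, rng)
    left_block = arm_b + left_spacer + left_ir_block

    dr = spec.right_end_direct_repeats
    dr_arm = random_dna(dr.arm_len, spec.gc_fraction, rng)
    dr_arm2 = _imperfect(dr_arm, dr.mismatches, rng)
    dr_gap = random_dna(dr.gap_len, spec.gc_fraction, rng)
    right_block = dr_arm + dr_gap + dr_arm2 + random_dna(3, spec.gc_fraction, rng) + arm_a + core

    tel = spec.telrl
    tel_arm = at_rich_dna(tel.outer_ir_arm, 0.8, rng)
    # 2-bp 'AA' spacers between the outer arms and the core are deliberately
    # non-mirrored (A vs comp(A)=T) so that fold-back identity through the
    # palindrome stops exactly at the core boundary.
    tel_site = tel_arm + "AA" + tel.core_palindrome + "AA" + revcomp(tel_arm)

    body = list(random_dna(n, spec.gc_fraction, rng))
    if len(left_block) + len(right_block) + len(tel_site) + 20 > n:
        raise ValueError("EVE too short for its terminal and telRL blocks")
    body[: len(left_block)] = left_block
    body[n - len(right_block) :] = right_block

    core_start = int(np.floor(tel.position_fraction * n))
    site_start = core_start - tel.outer_ir_arm - 2
    site_end = site_start + len(tel_site)
    if site_start < len(left_block) or site_end > n - len(right_block):
        raise ValueError("telRL position collides with the terminal blocks")
    body[site_start:site_end] = tel_site
    seq = "".join(body)

    eve_id = f"EVE_{spec.seed}"
    truth = TruthSet()
    truth.add(eve_id, "attP_core", n - len(core), n, f"core={core}")
    truth.add(eve_id, "attP_arm_left", 0, len(arm_b), "flank IR arm (revcomp of right arm)")
    truth.add(eve_id, "attP_arm_right", n - len(right_block) + len(dr_arm) + dr.gap_len
              + len(dr_arm2) + 3, n - len(core), "flank IR arm")
    truth.add(eve_id, "left_end_IR", len(arm_b) + len(left_spacer),
              len(arm_b) + len(left_spacer) + len(left_ir_block),
              f"arm={lir.arm_len},loop={lir.loop_len}")
    truth.add(eve_id, "right_end_DR", n - len(right_block),
              n - len(right_block) + 2 * dr.arm_len + dr.gap_len,
              f"arm={dr.arm_len},mismatches={dr.mismatches}")
    truth.add(eve_id, "telRL", core_start, core_start + len(tel.core_palindrome),
              f"palindrome={tel.core_palindrome},stagger={tel.stagger_nt}")
    truth.add(eve_id, "telRL_site", site_start, site_end, "outer IR + spacers + core")

    if spec.transposon is not None:
        seq, truth = _insert_transposon(eve_id, seq, truth, spec.transposon, rng)

    return SeqRecord(eve_id, seq, f"synthetic EVE length={len(seq)}"), truth


def _insert_transposon(
    eve_id: str, seq: str, truth: TruthSet, t: IS4Spec, rng: np.random.Generator
) -> tuple[str, TruthSet]:
    """Insert an IS4 block at 3/4 of the EVE, duplicating tsd_len target bases."""
    q = int(0.75 * len(seq))
    tsd = seq[q - t.tsd_len : q]
    tn = list(random_dna(t.length_bp, 0.45, rng))
    # Force the element's first/last bases to break any chance extension of the
    # duplication beyond tsd_len.
    if t.tsd_len > 0:
        if tn[0] == seq[q]:
            tn[0] = "A" if seq[q] != "A" else "C"
        before = seq[q - t.tsd_len - 1]
        if tn[-1] == before:
            tn[-1] = "A" if before != "A" else "C"
    tn = "".join(tn)
    new = seq[:q] + tn + seq[q - t.tsd_len :]
    shift = len(tn) + t.tsd_len
    shifted = TruthSet()
    for f in truth:
        if f.start >= q:
            shifted.features.append(f.shifted(shift))
        else:
            shifted.features.append(f)
    shifted.add(eve_id, "IS4", q, q + len(tn), f"len={len(tn)}")
    if t.tsd_len > 0:
        shifted.add(eve_id, "TSD", q - t.tsd_len, q, f"copy=left,seq={tsd}")
        shifted.add(eve_id, "TSD", q + len(tn), q + len(tn) + t.tsd_len, f"copy=right,seq={tsd}")
    return new, shifted


# ---------------------------------------------------------------------------
# integration / excision / hairpins


def integrate_eve(
    host: SeqRecord, eve: SeqRecord, site: int, core: str = "CC",
    eve_truth: TruthSet | None = None,
) -> tuple[SeqRecord, TruthSet]:
    """Integrate an EVE at `site`, where the host carries `core` ending at `site`.

    The integrated haplotype is host[:site] + eve + host[site:].  Because the
    EVE sequence ends with the viral core copy and the host contributes the
    core at the left junction, each junction carries exactly one core copy and
    no host sequence is duplicated beyond the shared core.
    """
    if site < len(core) or host.seq[site - len(core) : site] != core:
        raise ValueError(f"host does not carry core {core!r} ending at position {site}")
    if not eve.seq.endswith(core):
        raise ValueError("EVE sequence must end with the attP core")
    out_id = f"{host.id}+{eve.id}"
    seq = host.seq[:site] + eve.seq + host.seq[site:]
    truth = TruthSet()
    c = len(core)
    truth.add(out_id, "EVE_interval", site, site + len(eve.seq),
              f"eve={eve.id},core={core},host={host.id},site={site}")
    truth.add(out_id, "attL", site - c, site, f"core={core},copy=host")
    truth.add(out_id, "attR", site + len(eve.seq) - c, site + len(eve.seq),
              f"core={core},copy=virus")
    if eve_truth is not None:
        for f in eve_truth.get("telRL") + eve_truth.get("TSD") + eve_truth.get("IS4"):
            truth.features.append(f.shifted(site, out_id))
    return SeqRecord(out_id, seq, f"integrated at {site}"), truth


def excise_to_circle(
    integrated: SeqRecord, truth: TruthSet
) -> tuple[SeqRecord, SeqRecord]:
    """Excise the EVE: circular genome (origin at the attP core) + restored host.

    The circle keeps a single core copy at the re-formed attP junction; the
    restored host equals the pre-integration haplotype byte-for-byte.
    """
    iv = truth.one("EVE_interval", integrated.id)
    detail = dict(kv.split("=") for kv in iv.detail.split(","))
    core = detail["core"]
    c = len(core)
    i0, i1 = iv.start, iv.end
    eve = integrated.seq[i0:i1]
    circle = eve[-c:] + eve[:-c]  # rotate so the attP core starts the string
    restored = integrated.seq[:i0] + integrated.seq[i1:]
    return (
        SeqRecord(f"{integrated.id}|circle", circle, "excised circular genome"),
        SeqRecord(f"{integrated.id}|restored", restored, "restored EVE-free host"),
    )


def make_hairpin_templates(
    circle: SeqRecord, telrl: TelRlSpec, arm_len: int = 3000
) -> list[SeqRecord]:
    """Linear templates for the covalently closed telL/telR hairpin telomeres.

    Cleavage with a `stagger_nt` offset at the centre of the telRL palindrome
    and resealing yields hairpin ends; a read traversing such an end appears as
    arm + apex(stagger) + revcomp(arm).  The apex is the central stagger_nt
    bases of the core's top strand (the loop content is a modelling choice:
    only its length is fixed by the N15 analogy).
    """
    pos = _find_telrl_site(circle.seq, telrl)
    if pos == -1:
        raise ValueError("telRL core not found in circle")
    lc = len(telrl.core_palindrome)
    centre = pos + lc // 2
    st = min(telrl.stagger_nt, lc)
    a0 = centre - st // 2
    a1 = a0 + st
    apex = circle.seq[a0:a1]
    arm = min(arm_len, a0, len(circle.seq) - a1)
    left_arm = circle.seq[a0 - arm : a0]
    right_arm = circle.seq[a1 : a1 + arm]
    tel_l = left_arm + apex + revcomp(left_arm)
    tel_r = revcomp(right_arm) + revcomp(apex) + right_arm
    return [
        SeqRecord(f"{circle.id}|telL", tel_l, f"hairpin telL apex={a0}-{a1}"),
        SeqRecord(f"{circle.id}|telR", tel_r, f"hairpin telR apex={a0}-{a1}"),
    ]


def _find_telrl_site(seq: str, telrl: TelRlSpec) -> int:
    """Locate the telRL core: the palindrome occurrence embedded in the larger
    inverted repeat (chance occurrences of the short core elsewhere lack the
    flanking arms).  Falls back to the first occurrence if none qualifies."""
    lc = len(telrl.core_palindrome)
    arm = telrl.outer_ir_arm
    first = -1
    pos = seq.find(telrl.core_palindrome)
    while pos != -1:
        if first == -1:
            first = pos
        lo = pos - 2 - arm
        hi = pos + lc + 2
        if lo >= 0 and hi + arm <= len(seq):
            if seq[lo : lo + arm] == revcomp(seq[hi : hi + arm]):
                return pos
        pos = seq.find(telrl.core_palindrome, pos + 1)
    return first


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    templates: Mapping[str, Sequence[SeqRecord]], spec: ReadSimSpec
) -> list[SeqRecord]:
    """Sample reads uniformly along each template (wraparound for circles).

    Read count per template is Poisson(depth * len / mean_read_len); lengths
    are Normal(mean, sd) clipped to [min_read_len, template length].  Errors
    are uniform substitutions at error_rate (no indels).  Read ids encode
    class, template, coordinates and index for truth-aware tests.
    """
    rng = np.random.default_rng(spec.seed)
    mean_len, sd_len = spec.read_length
    reads: list[SeqRecord] = []
    for cls, depth in spec.depth_per_class.items():
        tlist = templates.get(cls, [])
        if depth > 0 and not tlist:
            raise ValueError(f"positive depth for class {cls!r} but no templates")
        circular = cls == "circle"
        for t in tlist:
            tlen = len(t.seq)
            doubled = t.seq + t.seq if circular else t.seq
            n_reads = rng.poisson(depth * tlen / mean_len)
            for i in range(n_reads):
                rl = int(np.clip(rng.normal(mean_len, sd_len), spec.min_read_len, tlen))
                start = int(rng.integers(0, tlen if circular else max(1, tlen - rl + 1)))
                seq = doubled[start : start + rl]
                if spec.error_rate > 0:
                    seq = _mutate(seq, spec.error_rate, rng)
                reads.append(
                    SeqRecord(f"{cls}|{t.id}|{start}|{rl}|{i}", seq,
                              f"class={cls} template={t.id}")
                )
    return reads


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    n_err = rng.binomial(len(seq), rate)
    if n_err:
        for pos in rng.choice(len(seq), size=n_err, replace=False):
            others = [b for b in "ACGT" if b != out[pos]]
            out[pos] = others[int(rng.integers(3))]
    return "".join(out)


# ---------------------------------------------------------------------------
# crosses


def simulate_cross(spec: CrossSpec) -> pd.DataFrame:
    """Segregate hemizygous EVE loci through meiosis.

    Each chromosome transmits one of its two homologs with probability 1/2,
    independently across chromosomes; a locus is inherited iff its homolog is
    transmitted.  The phenotype is symptomatic iff any active locus is present
    and a penetrance Bernoulli succeeds.  Returns a progeny table with one row
    per individual: id, sex, one present/absent column per locus, phenotype.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_progeny
    chrom_ids = sorted({c for _, c, _ in spec.loci})
    transmitted = {c: rng.integers(0, 2, size=n) for c in chrom_ids}
    data: dict[str, object] = {
        "individual": [f"P{i + 1:04d}" for i in range(n)],
        "sex": np.where(rng.integers(0, 2, size=n) == 0, "M", "F"),
    }
    present = {}
    for locus, chrom, homolog in spec.loci:
        present[locus] = transmitted[chrom] == homolog
        data[locus] = np.where(present[locus], "present", "absent")
    carrier = np.zeros(n, dtype=bool)
    for locus in spec.active_loci:
        carrier |= present[locus]
    expressed = rng.random(n) < spec.penetrance
    data["phenotype"] = np.where(carrier & expressed, "symptomatic", "asymptomatic")
    return pd.DataFrame(data)
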