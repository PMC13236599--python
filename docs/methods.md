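# Methods

This note documents the models, estimators and design choices behind
`evetrace`, in the order of the pipeline. Coordinates are 0-based half-open
throughout the package; GFF3 output alone is 1-based inclusive.

## The synthetic system

The generator (`simdata`) emulates a latently infected brown-algal genome at
desk scale. Defaults, with units and rationale:

| parameter | default | meaning |
|---|---|---|
| EVE length | 30,000 bp | scaled stand-in for the real 288–407 kb elements; every algorithm is length-agnostic, so tests run in seconds |
| EVE GC | 0.52 | the observed 51.5–52.5% composition of these elements |
| attP core | `CC` | the minimal host–virus homology at which integration occurs (`GC` variants supported) |
| attB context | `ATACC` | a weak `ATA` extension followed by the nearly invariant core; planted at least once per 10 kb of host |
| flanking IR | 10-bp arms, AT ≥ 0.8 | AT-rich inverted repeat flanking the core in attP |
| left-end IR | 12-bp arms, 6-bp loop | the conserved left-terminus repeat |
| right-end DRs | 10 bp ×2, 1 mismatch | imperfect direct repeats near the right terminus |
| telRL | `GAATTC` core, 15-bp outer IR arms, position 0.5, 6-nt stagger | palindromic telomere-resolution site inside a larger inverted repeat |
| IS4 transposon | 2,000 bp, 8-nt TSD | DDE/D-family element that duplicates its target site |
| read model | N(2000, 200) bp, substitutions only | keeps anchor detection exact-match testable; no indels or homopolymer artefacts |

An EVE is emitted in its **integrated orientation** and *ends* with the core:
at integration (`host[:site] + eve + host[site:]`, where the host carries the
core ending at `site`) the left junction's core copy is contributed by the
host attB and the right junction's by the viral attP, with no duplication
beyond the shared core. Excision inverts this exactly; the circle is
represented linearly with its origin at the attP core, and
integrate-then-excise restores the host byte-for-byte (property-tested over
100 seeds).

Three generator details are deliberate consequences of the biology being
modelled, fixed at design time so the worked examples are deterministic:

* the flanking-IR arm adjacent to the core ends in `T`, so virus-side
  junction homology with the planted `ATA`+core host context terminates at
  the core — the weak `ATA` extension is a host-side consensus feature, not a
  viral one;
* the telRL site is `arm + AA + palindrome + AA + revcomp(arm)` with
  non-mirrored 2-bp spacers, so exact-match identity through the palindrome
  stops at the core boundary;
* the transposon's first/last bases are forced to differ from the bases that
  would extend its target-site duplication beyond 8 nt.

What the generator does **not** emulate: Nanopore error structure (indels,
homopolymers), basecalling, diploid SNP background beyond EVE
presence/absence, nested insertions, or assembly fragmentation. Passing
tests therefore demonstrate correctness of the inference chain on clean,
truth-known inputs — not robustness to every artefact of real long-read
data (a uniform substitution mode up to 20% is available for sensitivity
checks).

## Junction resolution

Haplotypes are compared through maximal exact matches ≥ k (default k = 15),
chained colinearly by dynamic programming with score = summed anchor length;
overlap up to 100 bp is tolerated on either axis so junction microhomology
does not break the chain. An insertion is an adjacent anchor pair whose
query gap exceeds its reference gap; the flanking-anchor overlap *m* on the
free haplotype is the microhomology window (`ambiguity_shift`), and the
breakpoint is canonicalized **leftmost** on the host forward strand (the
variant-calling convention). Each flank must contribute ≥ 30 bp of anchor.
The mapper is validated against a quadratic brute-force maximal-exact-match
enumerator.

**Mechanism classification.** From the two haplotypes alone, an *m*-bp
target-site duplication and *m* bp of junction microhomology are the same
observable, so the classifier separates them by identity and magnitude:

1. if the conserved viral terminus locates the right junction and a shared
   string (1–10 nt) terminates both the host left flank and the viral end
   there → `recombinase_core` (core = that string);
2. else if *m* ≥ 4 → `dde_tsd` with `tsd_len = m` (the host target sequence
   flanks the element on both sides);
3. else a short overlap without viral ends is reported as a core; a zero
   overlap is `unclassified`.

The 4-nt TSD floor and 10-nt core ceiling guarantee a 2-bp core is never
called a duplication. The attachment-site quartet is cut around the located
junction: attB from the free haplotype centred on the core, attL/attR from
the two junctions, attP by joining the viral right terminus (which carries
the single core copy) to the left terminus — identical, by construction, to
a window across the excised circle's junction.

## Terminus profiles and consensus

Terminus models are **ungapped position log-odds profiles**:
`log2(((count+α)/(n+4α))/bg)` with α = 1 and background defaulting to
uniform (or the scanned contig's composition). Scanning slides the profile
over both strands, scores truncated model prefix/suffix windows at contig
edges, and reports non-overlapping hits greedily by score above
`0.6 × max achievable score`; the implementation is tested equal to
exhaustive window scoring. `dist_to_model_end` counts model columns between
the covered window and the terminal column (column 0 for a left-end model,
L−1 for a right-end model). Retention keeps hits with `hit_len ≥ 80` **and**
`dist_to_model_end ≤ 50`, both bounds inclusive; deduplication collapses
hits whose 100 bp of outward flanking sequence are string-identical. A
gapped profile-HMM scorer would be the natural extension point; the filters
transfer unchanged.

Logos report per-column frequencies and information content
`IC_j = 2 − H_j` bits without small-sample correction (a recorded divergence
from WebLogo-style rendering). The attB/attP consensus joins the host and
viral flank consensi across the core, where the core is the maximal run of
junction-terminal columns on which the attL host-side and attR viral-side
consensi agree — recovering `CC` (with the `ATA` context visible on the host
side only) from ≥ 100 noisy planted sites in the test suite.

## Excision signatures

* **attP spanning**: a read whose plus-strand anchors jump from within 500 bp
  of the EVE right terminus to within 500 bp of the left terminus with a
  read-coordinate gap ≤ 50 bp (both read orientations tried).
* **Fold-backs**: a read with a sense and an antisense anchor (each ≥ 100 bp)
  whose reference intervals overlap by ≥ 50% of the shorter arm (excluding
  inter-locus chimeras). The reversion coordinate is estimated from the
  read-coordinate overlap of the two arms: exact matching runs through a
  palindrome, so the arms overlap in the read by precisely the palindromic
  ambiguity around the apex, and the overlap midpoint projected through the
  sense anchor recovers the apex centre exactly on error-free reads (the
  innermost-edge midpoint, used when the arms do not overlap, sits on the
  palindrome edge and is only unbiased after averaging telL and telR reads).
* **telRL location**: reversion coordinates are clustered by single linkage
  (radius 20 bp); around the largest cluster's median, every boundary within
  ±window is tested for a maximal even palindrome of length 4–12 bp, the
  centre nearest the consensus wins, ties break leftmost, and the
  surrounding inverted repeat is annotated.
* **Coverage**: median anchor depth inside the element over the median
  outside. Note that with short reference flanks the outside median is
  depressed by read-edge ramp-down; fixtures keep flanks ≫ read length.
* **Verdicts**: circularization ≥ 3 spanning reads; linearization = telRL
  present with ≥ 3 supporting fold-backs; replication = ratio ≥ 2. The
  haploid (gametophyte) baseline is assumed; the detector reports the
  fold-back signature without claiming its molecular origin (covalently
  closed telomeres and replication intermediates are indistinguishable
  here), and no claim is made about the packaged genome form.

## Genetics

Hemizygous loci transmit with probability 1/2 per chromosome, independently
across chromosomes; loci on opposite homologs of one chromosome are mutually
exclusive. Linkage uses the 2×2 χ² with Yates continuity correction on by
default (the convention of the field's statistical environment), verified
against the closed form; segregation uses goodness-of-fit χ². Penetrance —
symptomatic carriers over carriers — is this package's modelling addition
for reconciling observed symptomatic fractions below the all-carriers
expectation; its Wilson score interval has exact coverage 95.06% at
penetrance 0.9 with ~250 carriers (computed by total probability over the
carrier and symptomatic binomials), which is what the calibration test
asserts — a hard ≥95%-of-1000-seeds bound would be a coin flip on a
quantity whose Monte-Carlo standard error is ~0.7%. Relative copy number is
`2^(Cq_ref − Cq_target)`.

## Problem sizes

Defaults were chosen so the full test suite runs in well under a minute and
the acceptance script in under one minute on a single CPU: 30-kb EVEs and
10-kb hosts for the demo chain; 4–8-kb EVEs, 450–700-bp reads and 20 seeds
per condition for the detection property suites; 2,000 replicate crosses of
200 progeny for the segregation distribution. Every algorithm is
length-agnostic, and real-scale parameters are reachable through the same
specs.

## Known limitations

No gapped alignment of diverged haplotypes (flanks must share near-identical
sequence); no nested EVE-within-EVE resolution (multiple inserts are
returned flagged); no SAM/BAM emission (anchor chains are internal); no
realistic error model; no multiple-testing correction across loci
(single-hypothesis design); logo IC lacks small-sample correction.
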