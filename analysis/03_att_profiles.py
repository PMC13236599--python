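"""Profile the EVE termini across a population of simulated insertions: one
EVE family (conserved termini, as for the near-identical elements sharing a
recent ancestor) integrated at many independent host sites.  Collect
attL/attR junction sequences, build left/right terminus log-odds profiles,
scan an EVE-bearing genome for termini, apply the retention filters
(>= 80 bp, within 50 bp of the model end), deduplicate identical flanks, and
reconstruct the attB/attP consensus and its core.  Writes results/attsites/."""

from pathlib import Path

import numpy as np

from evetrace import attsites as att
from evetrace import junctions as jn
from evetrace import simdata as sd

OUT = Path("results/attsites")
N_SITES = 60
FLANK = 100  # half-width of the attL/attR windows; termini are 100 bp
EVE_SEED = 4242


def usable_host(length: int, seed: int) -> tuple[sd.SeqRecord, int]:
    """A host with an attB context comfortably away from the contig edges."""
    while True:
        host = sd.make_host_genome(1, [length], gc=0.52, seed=seed)[0]
        sites = [s for s in sd.find_attB_sites(host) if 300 <= s <= length - 300]
        if sites:
            return host, sites[0]
        seed += 10_000


def collect_att_sites(n: int, seed0: int) -> tuple[list[str], list[str]]:
    eve, _ = sd.make_eve(sd.EveSpec(length_bp=1500, seed=EVE_SEED))
    attL, attR = [], []
    for s in range(n):
        host, site = usable_host(3000, seed0 + s)
        integrated, _ = sd.integrate_eve(host, eve, site, "CC")
        recs = jn.resolve_insertion(integrated, host, min_insert=400)
        rec = jn.classify_mechanism(recs[0], integrated, host, eve.seq[:60], eve.seq[-60:])
        q = jn.extract_att_quartet(rec, integrated, host, FLANK, eve.seq[:60], eve.seq[-60:])
        attL.append(q.attL)
        attR.append(q.attR)
    return attL, attR


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    attL, attR = collect_att_sites(N_SITES, seed0=100)

    left_prof = att.build_profile([s[FLANK:] for s in attL], side="left")
    right_prof = att.build_profile([s[:FLANK] for s in attR], side="right")
    left_prof.to_frame().to_csv(OUT / "left_profile.tsv", sep="\t", index=False)
    right_prof.to_frame().to_csv(OUT / "right_profile.tsv", sep="\t", index=False)

    # scan an independent EVE-bearing haplotype of the same family for termini
    host, site = usable_host(4000, 999)
    eve, _ = sd.make_eve(sd.EveSpec(length_bp=1500, seed=EVE_SEED))
    target, truth = sd.integrate_eve(host, eve, site, "CC")
    hits = att.scan_genome(right_prof, [target])
    kept = att.dedup_flanks(att.filter_hits(hits), [target], side="right", flank_w=100)
    iv = truth.one("EVE_interval")
    print(f"right-terminus scan: {len(hits)} raw hits, {len(kept)} after the "
          f"80 bp / 50 bp filters and flank dedup")
    for h in kept:
        print(f"  hit [{h.start}, {h.end}) strand {h.strand} score {h.score:.1f} bits "
              f"(truth right terminus ends at {iv.end})")

    logoL = att.make_logo([s[FLANK - 10 : FLANK + 10] for s in attL])
    logoR = att.make_logo([s[FLANK - 10 : FLANK + 10] for s in attR])
    logoL.frequencies.assign(IC=logoL.information).to_csv(OUT / "attL_logo.tsv", sep="\t", index=False)
    logoR.frequencies.assign(IC=logoR.information).to_csv(OUT / "attR_logo.tsv", sep="\t", index=False)

    attB, attP, core = att.infer_att_consensus(attL, attR)
    ic_last2 = att.make_logo([s[:FLANK] for s in attL]).information[-2:]
    print(f"consensus core: {core!r}; attB consensus ...{attB[FLANK - 8: FLANK + 8]}...")
    print(f"attL host-side junction columns IC = {np.round(ic_last2, 2)} bits "
          f"(the nearly invariant core dinucleotide)")

    irs = att.find_inverted_repeats(attP[FLANK - 15 : FLANK + 15], min_arm=5, max_loop=12)
    print(f"{len(irs)} inverted repeat(s) around the attP core; "
          f"AT fractions {[round(r.at_fraction, 2) for r in irs]}")
    with open(OUT / "consensus.txt", "w") as fh:
        fh.write(f"core\t{core}\nattB\t{attB}\nattP\t{attP}\n")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    main()
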