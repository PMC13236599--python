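"""Simulate the study system: a host chromosome, an integrated EVE, the
excised circle, hairpin-telomere templates, long reads from every molecule
class, and a segregating cross.  Writes FASTA/FASTQ/BED plus a JSON truth
manifest under results/sim/ for the downstream analysis steps."""

import json
from pathlib import Path

from evetrace import simdata as sd
from evetrace.io import write_bed, write_fasta, write_fastq

SEED = 1
OUT = Path("results/sim")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    host = sd.make_host_genome(1, [10_000], gc=0.52, seed=SEED)[0]
    eve, eve_truth = sd.make_eve(sd.EveSpec(length_bp=30_000, seed=SEED + 1))
    site = sd.find_attB_sites(host)[len(sd.find_attB_sites(host)) // 2]
    integrated, truth = sd.integrate_eve(host, eve, site, "CC", eve_truth)
    circle, restored = sd.excise_to_circle(integrated, truth)
    assert restored.seq == host.seq, "excision must restore the host exactly"
    hairpins = sd.make_hairpin_templates(circle, sd.TelRlSpec())

    reads = sd.simulate_reads(
        {"integrated": [integrated], "host_background": [integrated],
         "circle": [circle], "hairpin": hairpins},
        sd.ReadSimSpec(seed=SEED + 2),
    )
    cross = sd.simulate_cross(
        sd.CrossSpec(
            loci=[("EVEc", "chr16", 0), ("EVEb", "chr06", 0),
                  ("EVEd", "chr26", 0), ("EVEe", "chr03", 0)],
            active_loci=["EVEc"], n_progeny=200, seed=SEED + 3,
        )
    )

    write_fasta([host], OUT / "host.fasta")
    write_fasta([eve], OUT / "eve.fasta")
    write_fasta([integrated], OUT / "integrated.fasta")
    write_fasta([circle], OUT / "circle.fasta")
    write_fasta(
        [sd.SeqRecord("left", eve.seq[:60]), sd.SeqRecord("right", eve.seq[-60:])],
        OUT / "eve_ends.fasta",
    )
    write_fasta(hairpins, OUT / "hairpins.fasta")
    write_fastq(reads, OUT / "reads.fastq")
    write_bed(truth, OUT / "truth.bed")
    manifest = [
        {"genome_id": f.genome_id, "feature": f.feature, "start": f.start,
         "end": f.end, "detail": f.detail}
        for f in truth
    ]
    (OUT / "truth.json").write_text(json.dumps(manifest, indent=2) + "\n")
    cross.to_csv(OUT / "progeny.tsv", sep="\t", index=False)

    iv = truth.one("EVE_interval")
    frac = (cross["phenotype"] == "symptomatic").mean()
    print(f"host {len(host.seq)} bp; EVE {len(eve.seq)} bp integrated at {site} "
          f"(interval [{iv.start}, {iv.end}))")
    print(f"{len(reads)} reads across 4 molecule classes; "
          f"cross of {len(cross)} progeny, {frac:.1%} symptomatic")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    main()
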