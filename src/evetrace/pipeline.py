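"""End-to-end driver: simulate -> junctions -> attsites -> excision -> genetics.

Given a RunConfig, builds a host and an integrated EVE, resolves and
classifies the insertion, extracts the attachment-site quartet, simulates
long reads (symptomatic or not) and detects the excision signatures, then
segregates a cross and tests linkage.  Deterministic given the seed; outputs
are written with the config hash when out_dir is set.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import json

from . import excision, genetics, junctions, simdata
from .io import RunConfig, RunLog, write_bed, write_fasta, write_fastq


def run_pipeline(config: RunConfig, log: RunLog | None = None) -> dict:
    log = log or RunLog()
    log.log("start", config_hash=config.config_hash(), seed=config.seed)

    # --- simulate ---------------------------------------------------------
    host = simdata.make_host_genome(
        1, [config.host_length], gc=config.host_gc, seed=config.seed
    )[0]
    eve_spec = simdata.EveSpec(
        length_bp=config.eve_length,
        gc_fraction=config.eve_gc,
        attP_core=config.attP_core,
        seed=config.seed + 1,
    )
    eve, eve_truth = simdata.make_eve(eve_spec)
    sites = simdata.find_attB_sites(host)
    site = sites[len(sites) // 2]
    integrated, truth = simdata.integrate_eve(host, eve, site, config.attP_core, eve_truth)
    circle, restored = simdata.excise_to_circle(integrated, truth)
    hairpins = simdata.make_hairpin_templates(circle, eve_spec.telrl)
    depth = {
        "integrated": config.read_depth_integrated,
        "host_background": config.read_depth_host,
    }
    if config.symptomatic:
        depth["circle"] = config.read_depth_circle
        depth["hairpin"] = config.read_depth_hairpin
    reads = simdata.simulate_reads(
        {"integrated": [integrated], "host_background": [integrated],
         "circle": [circle], "hairpin": hairpins},
        simdata.ReadSimSpec(
            depth_per_class=depth,
            read_length=(config.read_length_mean, config.read_length_sd),
            error_rate=config.error_rate,
            seed=config.seed + 2,
        ),
    )
    log.log("simulated", n_reads=len(reads), site=site, eve_len=len(eve.seq))

    # --- junctions --------------------------------------------------------
    eve_left = eve.seq[:60]
    eve_right = eve.seq[-60:]
    records = junctions.resolve_insertion(integrated, host, k=config.k)
    for rec in records:
        junctions.classify_mechanism(rec, integrated, host, eve_left, eve_right)
    quartet = None
    for rec in records:
        if rec.mechanism == "recombinase_core":
            quartet = junctions.extract_att_quartet(
                rec, integrated, host, config.flank_w, eve_left, eve_right
            )
            break
    log.log("junctions", n_records=len(records),
            mechanisms=[r.mechanism for r in records])

    # --- excision ---------------------------------------------------------
    iv = truth.one("EVE_interval")
    span = excision.detect_attP_spanning(reads, integrated, (iv.start, iv.end), k=config.k)
    fb = excision.detect_foldback(reads, integrated, k=config.k)
    cluster = excision.cluster_reversions(fb) if fb else None
    telsite = (
        excision.locate_telrl(cluster.consensus_coord, integrated)
        if cluster is not None
        else None
    )
    cov = excision.coverage_ratio(reads, integrated, (iv.start, iv.end), k=config.k)
    report = excision.summarize(
        span, cluster, telsite, cov,
        min_span=config.min_span, min_fb=config.min_fb, min_ratio=config.min_ratio,
    )
    log.log("excision", n_span=report.n_span, n_foldback=report.n_foldback,
            coverage_ratio=report.coverage_ratio)

    # --- genetics ---------------------------------------------------------
    cross = simdata.simulate_cross(
        simdata.CrossSpec(
            loci=[("EVEc", "chr16", 0), ("EVEb", "chr06", 0),
                  ("EVEd", "chr26", 0), ("EVEe", "chr03", 0)],
            active_loci=["EVEc"],
            penetrance=config.penetrance,
            n_progeny=config.n_progeny,
            seed=config.seed + 3,
        )
    )
    linkage = genetics.linkage_test(genetics.linkage_table(cross, "EVEc"))
    log.log("genetics", chi2=linkage.chi2, p=linkage.p)

    results = {
        "junctions": records,
        "att_quartet": quartet,
        "excision_report": report,
        "linkage": linkage,
        "cross": cross,
        "truth": truth,
        "sequences": {
            "host": host, "eve": eve, "integrated": integrated,
            "circle": circle, "restored": restored,
        },
        "reads": reads,
    }
    if config.out_dir:
        _write_outputs(results, config, log)
    return results


def _write_outputs(results: dict, config: RunConfig, log: RunLog) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seqs = results["sequences"]
    write_fasta([seqs["host"], seqs["eve"], seqs["integrated"], seqs["circle"]],
                out / "genomes.fasta")
    write_fastq(results["reads"], out / "reads.fastq")
    write_bed(results["truth"], out / "truth.bed")
    truth_manifest = [
        {"genome_id": f.genome_id, "feature": f.feature, "start": f.start,
         "end": f.end, "detail": f.detail}
        for f in results["truth"]
    ]
    report = results["excision_report"]
    linkage = results["linkage"]
    payload = {
        "config_hash": config.config_hash(),
        "junctions": [asdict(r) for r in results["junctions"]],
        "excision": {
            "n_span": report.n_span,
            "n_foldback": report.n_foldback,
            "telrl_coord": report.telrl_coord,
            "palindrome_len": report.palindrome_len,
            "coverage_ratio": report.coverage_ratio,
            "circularization": report.circularization,
            "linearization": report.linearization,
            "replication": report.replication,
        },
        "linkage": {"chi2": linkage.chi2, "p": linkage.p,
                    "table": linkage.table.tolist()},
        "truth": truth_manifest,
    }
    (out / "results.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    results["cross"].to_csv(out / "progeny.tsv", sep="\t", index=False)
    log.log("written", out_dir=str(out))
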