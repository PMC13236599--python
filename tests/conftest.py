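"""Shared fixtures: small simulated worlds every stage can reuse."""

import pytest

from evetrace import simdata as sd


def usable_site(host, margin=200):
    sites = [s for s in sd.find_attB_sites(host) if margin <= s <= len(host.seq) - margin]
    if not sites:
        raise RuntimeError("no usable attB site; pick another seed")
    return sites[len(sites) // 2]


def make_world(host_len=4000, eve_len=8000, seed=7, transposon=None, telrl=None):
    """Host + EVE + integrated haplotype + truth, at test scale.

    Hosts whose attB contexts all fall too close to a contig edge are
    redrawn deterministically (the EVE seed is unchanged).
    """
    host_seed = seed
    while True:
        host = sd.make_host_genome(1, [host_len], gc=0.52, seed=host_seed)[0]
        if [s for s in sd.find_attB_sites(host) if 200 <= s <= host_len - 200]:
            break
        host_seed += 100_000
    spec = sd.EveSpec(length_bp=eve_len, seed=seed + 1, transposon=transposon,
                      telrl=telrl or sd.TelRlSpec())
    eve, eve_truth = sd.make_eve(spec)
    site = usable_site(host)
    integrated, truth = sd.integrate_eve(host, eve, site, spec.attP_core, eve_truth)
    return {
        "host": host, "eve": eve, "eve_truth": eve_truth, "spec": spec,
        "site": site, "integrated": integrated, "truth": truth,
    }


@pytest.fixture(scope="session")
def world():
    return make_world()


@pytest.fixture(scope="session")
def sym_reads(world):
    """Symptomatic read set: integrated + background + circle + hairpin classes."""
    circle, _ = sd.excise_to_circle(world["integrated"], world["truth"])
    hairpins = sd.make_hairpin_templates(circle, world["spec"].telrl, arm_len=1000)
    reads = sd.simulate_reads(
        {"integrated": [world["integrated"]], "host_background": [world["integrated"]],
         "circle": [circle], "hairpin": hairpins},
        sd.ReadSimSpec(
            depth_per_class={"integrated": 4, "host_background": 4,
                             "circle": 12, "hairpin": 15},
            read_length=(700, 70), seed=21,
        ),
    )
    return {"reads": reads, "circle": circle, "hairpins": hairpins}
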