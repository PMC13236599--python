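"""The generator's outputs must validate against their own truth records."""

import numpy as np
import pytest
from scipy import stats

from evetrace import simdata as sd
from evetrace.util import gc_fraction, is_palindrome, revcomp

from conftest import make_world


class TestHostGenome:
    def test_seed_determinism(self):
        a = sd.make_host_genome(1, [10_000], gc=0.5, seed=7)
        b = sd.make_host_genome(1, [10_000], gc=0.5, seed=7)
        assert a[0].seq == b[0].seq
        c = sd.make_host_genome(1, [10_000], gc=0.5, seed=8)
        assert c[0].seq != a[0].seq

    def test_realized_gc(self):
        host = sd.make_host_genome(1, [50_000], gc=0.52, seed=3)[0]
        assert 0.50 <= gc_fraction(host.seq) <= 0.54

    def test_attB_context_every_10kb(self):
        host = sd.make_host_genome(1, [40_000], gc=0.52, seed=5)[0]
        for b0 in range(0, 40_000, 10_000):
            assert sd.ATT_B_CONTEXT in host.seq[b0 : b0 + 10_000]

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            sd.make_host_genome(1, [0], gc=0.5, seed=1)


class TestMakeEve:
    def test_telrl_truth_is_palindromic(self):
        eve, truth = sd.make_eve(sd.EveSpec(length_bp=6000, seed=2))
        tel = truth.one("telRL")
        core = eve.seq[tel.start : tel.end]
        assert is_palindrome(core)
        assert tel.start == int(0.5 * 6000)

    def test_custom_palindrome_length(self):
        spec = sd.EveSpec(length_bp=6000, seed=2,
                          telrl=sd.TelRlSpec(core_palindrome="GAATTC"))
        eve, truth = sd.make_eve(spec)
        tel = truth.one("telRL")
        assert tel.end - tel.start == 6

    def test_non_palindromic_core_rejected(self):
        with pytest.raises(ValueError):
            sd.TelRlSpec(core_palindrome="GATTTC")

    def test_terminal_blocks(self):
        eve, truth = sd.make_eve(sd.EveSpec(length_bp=6000, seed=4))
        assert eve.seq.endswith("CC")
        ir = truth.one("left_end_IR")
        block = eve.seq[ir.start : ir.end]
        arm = (len(block) - 6) // 2
        assert block[:arm] == revcomp(block[-arm:])

    def test_transposon_tsd_copies_match(self):
        eve, truth = sd.make_eve(sd.EveSpec(length_bp=6000, seed=4,
                                            transposon=sd.IS4Spec(length_bp=500)))
        left, right = truth.get("TSD")
        assert eve.seq[left.start : left.end] == eve.seq[right.start : right.end]
        assert left.end - left.start == 8
        is4 = truth.one("IS4")
        assert (left.end, right.start) == (is4.start, is4.end)

    def test_telrl_collision_rejected(self):
        with pytest.raises(ValueError):
            sd.make_eve(sd.EveSpec(length_bp=6000, seed=1,
                                   telrl=sd.TelRlSpec(position_fraction=0.003)))


class TestIntegrationExcision:
    def test_toy_layout(self):
        host = sd.SeqRecord("h", "AAAATACCGGGG")
        eve, _ = sd.make_eve(sd.EveSpec(length_bp=100, seed=1, flank_ir=sd.IrSpec(4, 2),
                                        left_end_ir=sd.IrSpec(4, 2),
                                        right_end_direct_repeats=sd.DirectRepeatSpec(4, 2, 1),
                                        telrl=sd.TelRlSpec(outer_ir_arm=4)))
        integrated, truth = sd.integrate_eve(host, eve, 8, "CC")
        assert len(integrated.seq) == 12 + 100
        # both junction-spanning 10-mers contain 'CC' at the breakpoint
        assert integrated.seq[3:13].count("CC") >= 1 and integrated.seq[6:8] == "CC"
        assert integrated.seq[106:108] == "CC"  # viral core copy at the right junction

    def test_core_missing_rejected(self):
        host = sd.SeqRecord("h", "AAAATACCGGGG")
        eve, _ = sd.make_eve(sd.EveSpec(length_bp=200, seed=1, telrl=sd.TelRlSpec(outer_ir_arm=4)))
        with pytest.raises(ValueError):
            sd.integrate_eve(host, eve, 3, "CC")

    @pytest.mark.parametrize("seed", range(25))
    def test_integrate_excise_roundtrip(self, seed):
        w = make_world(host_len=2000, eve_len=1200, seed=seed)
        circle, restored = sd.excise_to_circle(w["integrated"], w["truth"])
        assert restored.seq == w["host"].seq
        assert len(circle.seq) == len(w["eve"].seq)
        assert circle.seq.startswith("CC")  # origin at the attP core

    def test_circle_rotation_invariance(self):
        w = make_world(host_len=2000, eve_len=1200, seed=3)
        circle, _ = sd.excise_to_circle(w["integrated"], w["truth"])
        junction = circle.seq[-10:] + circle.seq[:10]
        for off in (0, 17, 600, len(circle.seq) - 5):
            rot = circle.seq[off:] + circle.seq[:off]
            assert junction in rot + rot


class TestHairpins:
    def test_hairpin_symmetry(self, world):
        circle, _ = sd.excise_to_circle(world["integrated"], world["truth"])
        tel = world["spec"].telrl
        comp = dict(zip("ACGT", "TGCA"))
        for t in sd.make_hairpin_templates(circle, tel, arm_len=300):
            s = t.seq
            c = len(s) // 2  # apex centre
            st = tel.stagger_nt
            assert len(s) == 2 * 300 + st
            for k in range(st // 2, 250):  # outside the apex, inside the arms
                assert s[c + k] == comp[s[c - k - 1]]

    def test_zero_stagger_perfect_foldback(self, world):
        circle, _ = sd.excise_to_circle(world["integrated"], world["truth"])
        tel = sd.TelRlSpec(stagger_nt=0)
        t = sd.make_hairpin_templates(circle, tel, arm_len=100)[0]
        assert t.seq[:100] == revcomp(t.seq[100:])

    def test_core_absent_rejected(self):
        with pytest.raises(ValueError):
            sd.make_hairpin_templates(
                sd.SeqRecord("c", "ACGT" * 100), sd.TelRlSpec(core_palindrome="GCATATGC")
            )


class TestReads:
    def test_error_free_circle_reads_are_substrings(self, world):
        circle, _ = sd.excise_to_circle(world["integrated"], world["truth"])
        reads = sd.simulate_reads(
            {"circle": [circle]},
            sd.ReadSimSpec(depth_per_class={"circle": 5}, read_length=(800, 80), seed=5),
        )
        doubled = circle.seq + circle.seq
        assert reads and all(r.seq in doubled for r in reads)

    def test_read_count_poisson(self, world):
        circle, _ = sd.excise_to_circle(world["integrated"], world["truth"])
        depth, mean_len = 20, 500
        reads = sd.simulate_reads(
            {"circle": [circle]},
            sd.ReadSimSpec(depth_per_class={"circle": depth}, read_length=(mean_len, 50),
                           seed=9),
        )
        lam = depth * len(circle.seq) / mean_len
        assert abs(len(reads) - lam) <= 3 * np.sqrt(lam)

    def test_seed_determinism(self, world):
        spec = sd.ReadSimSpec(depth_per_class={"integrated": 3}, seed=4)
        a = sd.simulate_reads({"integrated": [world["integrated"]]}, spec)
        b = sd.simulate_reads({"integrated": [world["integrated"]]}, spec)
        assert [(r.id, r.seq) for r in a] == [(r.id, r.seq) for r in b]

    def test_error_rate_applied(self, world):
        spec = sd.ReadSimSpec(depth_per_class={"integrated": 3}, error_rate=0.05, seed=4)
        reads = sd.simulate_reads({"integrated": [world["integrated"]]}, spec)
        ref = world["integrated"].seq
        mism = total = 0
        for r in reads:
            cls, tid, start, rl, i = r.id.split("|")
            true = ref[int(start) : int(start) + int(rl)]
            mism += sum(a != b for a, b in zip(true, r.seq))
            total += len(true)
        assert 0.03 < mism / total < 0.07

    def test_missing_templates_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_reads({}, sd.ReadSimSpec(depth_per_class={"circle": 5}))


class TestCross:
    def test_sixteen_class_frequencies(self):
        spec = sd.CrossSpec(
            loci=[("a", "c1", 0), ("b", "c2", 0), ("c", "c3", 0), ("d", "c4", 0)],
            active_loci=["a"], n_progeny=10_000, seed=1,
        )
        table = sd.simulate_cross(spec)
        classes = table[["a", "b", "c", "d"]].apply(tuple, axis=1)
        counts = classes.value_counts()
        assert len(counts) == 16
        chi2, p = stats.chisquare(counts.values)
        assert p > 0.001

    def test_homologue_exclusive_pair(self):
        spec = sd.CrossSpec(
            loci=[("EVEf", "c15", 0), ("EVEg", "c17", 0),
                  ("EVEh", "c23", 0), ("EVEi", "c23", 1)],
            active_loci=["EVEh", "EVEi"], n_progeny=500, seed=2,
        )
        t = sd.simulate_cross(spec)
        h = t["EVEh"] == "present"
        i = t["EVEi"] == "present"
        assert (h ^ i).all()  # exactly one of the pair in every progeny
        n_loci = sum((t[l] == "present") for l in ("EVEf", "EVEg", "EVEh", "EVEi"))
        assert (n_loci >= 1).all()  # every progeny inherits at least one EVE
        assert (t["phenotype"] == "symptomatic").all()

    def test_penetrance_scales_symptoms(self):
        spec = sd.CrossSpec(loci=[("x", "c1", 0)], active_loci=["x"],
                            penetrance=0.5, n_progeny=4000, seed=3)
        t = sd.simulate_cross(spec)
        frac = (t["phenotype"] == "symptomatic").mean()
        assert 0.2 < frac < 0.3  # half carriers, half expressed

    def test_unknown_active_locus_rejected(self):
        with pytest.raises(ValueError):
            sd.CrossSpec(loci=[("a", "c1", 0)], active_loci=["z"])


def test_truth_features_validate(world):
    """Every planted feature's sequence content matches its record."""
    eve, truth = world["eve"], world["eve_truth"]
    tel = truth.one("telRL")
    assert is_palindrome(eve.seq[tel.start : tel.end])
    core = truth.one("attP_core")
    assert eve.seq[core.start : core.end] == "CC"
    integ, itruth = world["integrated"], world["truth"]
    attL = itruth.one("attL")
    attR = itruth.one("attR")
    assert attL.end <= attR.start
    assert integ.seq[attL.start : attL.end] == "CC"
    assert integ.seq[attR.start : attR.end] == "CC"
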