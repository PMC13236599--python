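"""Profile construction against hand computations, scanning against an
exhaustive oracle, and the screen's retention filters at their boundaries."""

import numpy as np
import pytest

from evetrace import attsites as att
from evetrace import junctions as jn
from evetrace import simdata as sd
from evetrace.util import SeqRecord, random_dna, revcomp

from conftest import usable_site


class TestBuildProfile:
    def test_hand_computed_log_odds(self):
        prof = att.build_profile(["AC", "AT"], side="left", alpha=0.0)
        lo = prof.log_odds
        assert lo[0, 0] == pytest.approx(2.0)  # A in column 1: log2(1/0.25)
        assert lo[1, 1] == pytest.approx(1.0)  # C in column 2: log2(0.5/0.25)
        assert lo[3, 1] == pytest.approx(1.0)  # T in column 2
        assert np.isneginf(lo[2, 0])  # G never observed, alpha 0

    def test_single_sequence_consensus(self):
        prof = att.build_profile(["GATTACA"], side="right")
        assert prof.consensus == "GATTACA"

    def test_uniform_column_zero_log_odds(self):
        prof = att.build_profile(["A", "C", "G", "T"], side="left", alpha=0.0)
        assert np.allclose(prof.log_odds, 0.0)

    def test_finite_log_odds_with_pseudocount(self):
        prof = att.build_profile(["AAAA", "AAAA"], side="left", alpha=1.0)
        assert np.isfinite(prof.log_odds).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            att.build_profile(["AC", "ACT"], side="left")


class TestLogo:
    def test_information_content_cases(self):
        logo = att.make_logo(["CA", "CT"])
        assert logo.information[0] == pytest.approx(2.0)  # invariant column
        assert logo.information[1] == pytest.approx(1.0)  # {A: .5, T: .5}
        logo2 = att.make_logo(["A", "C", "G", "T"])
        assert logo2.information[0] == pytest.approx(0.0)  # equifrequent

    def test_ic_bounds_and_frequency_sums(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seqs = [random_dna(15, rng.uniform(0.2, 0.8), rng) for _ in range(8)]
            logo = att.make_logo(seqs)
            assert ((logo.information >= -1e-9) & (logo.information <= 2 + 1e-9)).all()
            assert np.allclose(logo.frequencies.sum(axis=1), 1.0)


class TestScanGenome:
    @staticmethod
    def naive_full_window_scores(profile, seq):
        M = profile.log_odds
        L = profile.length
        idx = {b: i for i, b in enumerate("ACGT")}
        return [
            sum(M[idx[seq[i + j]], j] for j in range(L))
            for i in range(len(seq) - L + 1)
        ]

    def test_matches_exhaustive_window_scoring(self):
        rng = np.random.default_rng(4)
        seqs = [random_dna(40, 0.5, rng) for _ in range(6)]
        prof = att.build_profile(seqs, side="right")
        contig = SeqRecord(
            "c", random_dna(3000, 0.5, rng) + prof.consensus + random_dna(500, 0.5, rng)
        )
        hits = att.scan_genome(prof, [contig], score_min=0.5 * prof.max_score,
                               allow_partial=False)
        naive = {}
        for strand in "+-":
            s = contig.seq if strand == "+" else revcomp(contig.seq)
            for i, sc in enumerate(self.naive_full_window_scores(prof, s)):
                if sc >= 0.5 * prof.max_score:
                    start = i if strand == "+" else len(s) - i - prof.length
                    naive[(start, strand)] = sc
        # every reported hit is a naive hit with the same score, and the top
        # naive window is reported
        for h in hits:
            assert naive[(h.start, h.strand)] == pytest.approx(h.score)
        best = max(naive.items(), key=lambda kv: kv[1])
        assert any(h.start == best[0][0] and h.strand == best[0][1] for h in hits)

    def test_planted_consensus_is_top_hit(self):
        rng = np.random.default_rng(5)
        seqs = [random_dna(50, 0.5, rng) for _ in range(4)]
        prof = att.build_profile(seqs, side="left")
        plant_at = 6000
        contig_seq = random_dna(10_000, 0.5, rng)
        contig = SeqRecord("c", contig_seq[:plant_at] + prof.consensus + contig_seq[plant_at + 50 :])
        hits = att.scan_genome(prof, [contig])
        top = max(hits, key=lambda h: h.score)
        assert (top.start, top.strand) == (plant_at, "+")
        assert top.score == pytest.approx(prof.max_score)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(6)
        seqs = [random_dna(50, 0.5, rng) for _ in range(4)]
        prof = att.build_profile(seqs, side="left")
        contig_seq = random_dna(3000, 0.5, rng)
        contig = SeqRecord("c", contig_seq[:1000] + prof.consensus + contig_seq[1050:])
        fwd = att.scan_genome(prof, [contig])
        rev = att.scan_genome(prof, [SeqRecord("rc", revcomp(contig.seq))])
        top_f = max(fwd, key=lambda h: h.score)
        top_r = max(rev, key=lambda h: h.score)
        assert top_f.score == pytest.approx(top_r.score)
        assert (top_f.strand, top_r.strand) == ("+", "-")
        assert top_r.start == len(contig.seq) - top_f.end

    def test_random_contig_no_hits_at_high_threshold(self):
        rng = np.random.default_rng(7)
        seqs = [random_dna(60, 0.5, rng) for _ in range(3)]
        prof = att.build_profile(seqs, side="left")
        for s in range(5):
            contig = SeqRecord("c", random_dna(5000, 0.5, np.random.default_rng(100 + s)))
            hits = att.scan_genome(prof, [contig], score_min=0.8 * prof.max_score,
                                   allow_partial=False)
            assert hits == []

    def test_partial_hit_distance_at_contig_edge(self):
        """A terminus truncated by the contig edge reports its missing model
        columns as dist_to_model_end."""
        rng = np.random.default_rng(8)
        seqs = [random_dna(60, 0.5, rng) for _ in range(3)]
        prof = att.build_profile(seqs, side="left")
        # contig starts 25 columns INTO the model: terminal column 0 missing
        contig = SeqRecord("c", prof.consensus[25:] + random_dna(400, 0.5, rng))
        hits = att.scan_genome(prof, [contig], score_min=0.4 * prof.max_score)
        edge = [h for h in hits if h.start == 0 and h.hit_len == 35]
        assert edge and edge[0].dist_to_model_end == 25


class TestFilters:
    def make_hit(self, length, dist):
        return att.TerminusHit("c", 0, length, "+", 10.0, length, dist)

    def test_boundary_inclusive(self):
        hits = [
            self.make_hit(79, 0),   # too short
            self.make_hit(120, 51),  # too far from the model end
            self.make_hit(80, 50),  # boundary: retained (inclusive)
            self.make_hit(200, 0),
        ]
        kept = att.filter_hits(hits)
        assert [h.hit_len for h in kept] == [80, 200]

    def test_idempotent_and_order_preserving(self):
        hits = [self.make_hit(100, 0), self.make_hit(90, 10), self.make_hit(300, 3)]
        once = att.filter_hits(hits)
        assert att.filter_hits(once) == once
        assert once == hits


class TestDedupFlanks:
    def test_identical_flanks_collapse(self):
        rng = np.random.default_rng(9)
        flank = random_dna(100, 0.5, rng)
        term = random_dna(80, 0.5, rng)
        spacer = random_dna(50, 0.5, rng)
        contig = SeqRecord("c", flank + term + spacer + flank + term)
        h1 = att.TerminusHit("c", 100, 180, "+", 5.0, 80, 0)
        h2 = att.TerminusHit("c", 330, 410, "+", 5.0, 80, 0)
        kept = att.dedup_flanks([h1, h2], [contig], side="left")
        assert kept == [h1]  # first by coordinate represents the pair

    def test_different_flanks_kept(self):
        rng = np.random.default_rng(10)
        term = random_dna(80, 0.5, rng)
        contig = SeqRecord("c", random_dna(100, 0.5, rng) + term
                           + random_dna(100, 0.5, rng) + term)
        h1 = att.TerminusHit("c", 100, 180, "+", 5.0, 80, 0)
        h2 = att.TerminusHit("c", 280, 360, "+", 5.0, 80, 0)
        kept = att.dedup_flanks([h1, h2], [contig], side="left")
        assert kept == [h1, h2]

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        contig = SeqRecord("c", random_dna(500, 0.5, rng))
        hits = [att.TerminusHit("c", 150, 230, "+", 5.0, 80, 0),
                att.TerminusHit("c", 300, 380, "+", 5.0, 80, 0)]
        once = att.dedup_flanks(hits, [contig], side="right")
        assert att.dedup_flanks(once, [contig], side="right") == once


class TestTrimAlignment:
    def test_identical_rows_untouched(self):
        rows = ["ACGTACGT"] * 5
        assert att.trim_alignment(rows) == rows

    def test_gappy_terminal_columns_removed(self):
        rng = np.random.default_rng(12)
        core = [random_dna(30, 0.5, rng)] * 10
        rows = [core[0] + ("-" * 20 if i else random_dna(20, 0.5, rng))
                for i in range(10)]
        trimmed = att.trim_alignment(rows, occupancy_min=0.5)
        assert all(r == core[0] for r in trimmed)

    def test_single_row_warns(self):
        with pytest.warns(UserWarning):
            out = att.trim_alignment(["ACGT"])
        assert out == ["ACGT"]

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            att.trim_alignment([])


class TestAttConsensus:
    def test_fixed_cc_junction_recovers_core(self):
        rng = np.random.default_rng(13)
        attL = [random_dna(18, 0.5, rng) + "CC" + random_dna(20, 0.5, rng)
                for _ in range(30)]
        viral_right = random_dna(18, 0.5, rng)
        attR = [viral_right + "CC" + random_dna(20, 0.5, rng) for _ in range(30)]
        _, _, core = att.infer_att_consensus(attL, attR)
        assert core == "CC"

    def test_recovery_from_planted_context_with_noise(self):
        """100 EVE family insertions at 'ATACC' sites, 10% flank noise: the
        consensus ends in the CC core with >= 1.5 bits per column."""
        rng = np.random.default_rng(14)
        eve, _ = sd.make_eve(sd.EveSpec(length_bp=400, seed=50,
                                        telrl=sd.TelRlSpec(position_fraction=0.4)))
        attL, attR = [], []
        for _ in range(100):
            flank_l = list(random_dna(20, 0.5, rng))
            flank_r = list(random_dna(20, 0.5, rng))
            ctx = list("ATA")
            for arr in (flank_l, flank_r, ctx):
                for i in range(len(arr)):
                    if rng.random() < 0.10:
                        arr[i] = "ACGT"[rng.integers(4)]
            host_left = "".join(flank_l) + "".join(ctx) + "CC"
            attL.append(host_left[-20:] + eve.seq[:20])
            attR.append(eve.seq[-20:] + "".join(flank_r))
        _, _, core = att.infer_att_consensus(attL, attR)
        assert core.endswith("CC")
        logo = att.make_logo([s[:20] for s in attL])
        assert logo.information[-1] >= 1.5 and logo.information[-2] >= 1.5

    def test_single_pair_matches_quartet(self):
        host = sd.make_host_genome(1, [3000], gc=0.52, seed=31)[0]
        eve, _ = sd.make_eve(sd.EveSpec(length_bp=1200, seed=32))
        site = usable_site(host)
        integ, _ = sd.integrate_eve(host, eve, site, "CC")
        rec = jn.resolve_insertion(integ, host, min_insert=400)[0]
        jn.classify_mechanism(rec, integ, host, eve.seq[:60], eve.seq[-60:])
        q = jn.extract_att_quartet(rec, integ, host, 20, eve.seq[:60], eve.seq[-60:])
        attB, attP, core = att.infer_att_consensus([q.attL], [q.attR])
        assert attB == q.attB
        assert attP == q.attP
        assert core == q.core == "CC"


class TestRepeats:
    def test_palindrome_special_case(self):
        hits = att.find_inverted_repeats("GAATTC", min_arm=3, max_loop=0)
        assert any(h.arm_len == 3 and h.loop_len == 0 and h.mismatches == 0
                   for h in hits)

    def test_at_rich_inverted_repeat(self):
        hits = att.find_inverted_repeats("AAAATTTT", min_arm=4, max_loop=0)
        top = max(hits, key=lambda h: h.arm_len)
        assert (top.arm_len, top.loop_len, top.at_fraction) == (4, 0, 1.0)

    def test_direct_repeat(self):
        hits = att.find_inverted_repeats("ACGTACGT", min_arm=4, max_loop=0,
                                         kind="direct")
        assert any(h.arm_len == 4 and h.loop_len == 0 for h in hits)

    def test_inverted_repeat_with_loop_and_mismatch(self):
        arm = "ATTTACGGAT"
        seq = "G" + arm + "CCCC" + revcomp(arm) + "G"
        (hit,) = [h for h in att.find_inverted_repeats(seq, min_arm=8, max_loop=6)
                  if h.arm_len >= 8]
        assert hit.loop_len == 4 and hit.arm_len == 10
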