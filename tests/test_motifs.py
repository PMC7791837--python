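import itertools
import math
from collections import Counter

import numpy as np
import pytest

from grnrewire.core import GeneModel, GenomicInterval, revcomp
from grnrewire.motifs import (
    BASES,
    PSSM,
    MotifHit,
    ScanResult,
    assign_confidence,
    bh_qvalues,
    build_pssms,
    call_significant,
    counts_from_sites,
    extract_promoter,
    extrapolate_site,
    retain_proximal,
    scan,
    shuffle_promoters,
    window_density,
)


def brute_force_pvalue(pssm, score, rc=False):
    """Exhaustive enumeration oracle: P(window score >= s) under background."""
    matrix = pssm.reverse_complement_matrix() if rc else pssm.log_odds
    w = matrix.shape[1]
    total = 0.0
    for seq in itertools.product(range(4), repeat=w):
        s = sum(matrix[b, j] for j, b in enumerate(seq))
        if s >= score - 1e-9:
            total += math.prod(pssm.background[b] for b in seq)
    return total


class TestPSSM:
    def test_frequency_columns_sum_to_one(self, smooth_pssm):
        np.testing.assert_allclose(smooth_pssm.freq.sum(axis=0), 1.0, atol=1e-9)

    def test_background_equal_frequency_scores_zero(self):
        # counts chosen so freq == background exactly after pseudocounts
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        counts = np.tile(bg[:, None] * 1000 - 0.25, (1, 5))
        pssm = PSSM("t", counts, background=bg)
        np.testing.assert_allclose(pssm.log_odds, 0.0, atol=1e-12)

    def test_width_and_provenance_validation(self):
        with pytest.raises(ValueError, match="width"):
            PSSM("t", np.ones((4, 3)))
        with pytest.raises(ValueError, match="provenance"):
            PSSM("t", np.ones((4, 5)), provenance="XX")

    @pytest.mark.parametrize("width", [4, 5, 6])
    def test_exact_pvalue_equals_enumeration(self, width):
        rng = np.random.default_rng(width)
        counts = rng.integers(1, 20, (4, width)).astype(float)
        pssm = PSSM("t", counts, background=[0.3, 0.2, 0.2, 0.3])
        for s in np.linspace(pssm.min_score(), pssm.max_score(), 17):
            dp = pssm.exact_pvalue(float(s))
            brute = brute_force_pvalue(pssm, float(s))
            assert abs(dp - brute) <= 10 * pssm.granularity

    def test_pvalue_boundaries_and_monotonicity(self, smooth_pssm):
        assert smooth_pssm.exact_pvalue(smooth_pssm.min_score()) == 1.0
        assert smooth_pssm.exact_pvalue(smooth_pssm.max_score() + 1.0) == 0.0
        grid = np.linspace(smooth_pssm.min_score(), smooth_pssm.max_score(), 60)
        ps = [smooth_pssm.exact_pvalue(float(s)) for s in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_zero_pseudocount_consensus_log_odds(self):
        # identical sites with no smoothing: unit frequency columns and the
        # consensus scores sum(log(1/bg))
        pssm = PSSM("t", counts_from_sites(["ACGT"] * 3), pseudocount=0.0)
        assert np.array_equal(pssm.freq.max(axis=0), np.ones(4))
        expected = sum(math.log(1 / 0.25) for _ in range(4))
        consensus_score = sum(
            pssm.log_odds["ACGT".index(b), j] for j, b in enumerate("ACGT")
        )
        assert consensus_score == pytest.approx(expected)
        with pytest.raises(ValueError, match="non-finite"):
            pssm.exact_pvalue(0.0)


class TestPromoterExtraction:
    def test_plus_strand_5kb(self):
        contig = "A" * 10000
        gene = GeneModel("g", "sp", GenomicInterval("c", 6000, 7000, "+"))
        seq, iv = extract_promoter(gene, contig)
        assert (iv.start, iv.end) == (1000, 6000)
        assert len(seq) == 5000

    def test_minus_strand_revcomp(self):
        contig = "".join(np.random.default_rng(0).choice(list("ACGT"), 10000))
        gene = GeneModel("g", "sp", GenomicInterval("c", 50, 101, "-"))
        seq, iv = extract_promoter(gene, contig)
        assert gene.tss == 100
        assert (iv.start, iv.end) == (101, 5101)
        assert seq == revcomp(contig[101:5101]).upper()

    def test_truncation_at_contig_start(self):
        contig = "A" * 10000
        gene = GeneModel("g", "sp", GenomicInterval("c", 2000, 3000, "+"))
        seq, _ = extract_promoter(gene, contig)
        assert len(seq) == 2000


class TestExtrapolation:
    def test_verbatim_site_identity_one(self):
        promoter = "A" * 50 + "CGTTAATTAC" + "A" * 40
        m = extrapolate_site("tf", "sp", "CGTTAATTAC", promoter)
        assert m.identity == 1.0
        assert m.start == 50

    def test_boundary_identity_07_accepted(self):
        # brute-force-verifiable: best window has exactly 3/10 mismatches
        site = "GGGGGGGGGG"
        promoter = "A" * 30 + "GGGGGGGCCC" + "A" * 30
        m = extrapolate_site("tf", "sp", site, promoter)
        assert m is not None
        assert m.identity == pytest.approx(0.7)

    def test_below_threshold_rejected(self):
        site = "GGGGGGGGGG"
        promoter = "A" * 30 + "GGGGGGCCCC" + "A" * 30  # best 6/10
        assert extrapolate_site("tf", "sp", site, promoter) is None

    def test_best_match_equals_brute_force(self):
        rng = np.random.default_rng(3)
        promoter = "".join(rng.choice(list("ACGT"), 200))
        site = "".join(rng.choice(list("ACGT"), 8))
        m = extrapolate_site("tf", "sp", site, promoter, min_identity=0.0)
        best = 0.0
        for i in range(len(promoter) - 7):
            win = promoter[i : i + 8]
            for probe in (site, revcomp(site)):
                best = max(best, sum(a == b for a, b in zip(win, probe)) / 8)
        assert m.identity == pytest.approx(best)

    def test_minus_strand_match_reported_in_motif_frame(self):
        site = "CGTTAATTAC"
        promoter = "A" * 20 + revcomp(site) + "A" * 20
        m = extrapolate_site("tf", "sp", site, promoter)
        assert m.strand == "-"
        assert m.sequence == site


class TestBuildPssms:
    def test_species_with_three_sites_gets_cs(self):
        sites = {"sp1": ["ACGTA", "ACGTA", "ACGTT"], "sp2": ["ACGTA", "ACGTC"]}
        pssms = build_pssms("tf", sites)
        assert pssms["sp1"].provenance == "CS"
        assert pssms["sp1"].counts.sum() == 15  # 3 sites x width 5

    def test_species_below_three_gets_pooled_cw(self):
        sites = {
            "sp1": ["ACGTA", "ACGTA", "ACGTT"],
            "sp2": ["ACGTA", "ACGTC"],
            "sp3": ["ACGTA", "ACGTG"],
        }
        pssms = build_pssms("tf", sites)
        assert pssms["sp2"].provenance == "CW"
        assert pssms["sp2"].counts.sum() == 35  # pooled 7 sites x width 5
        assert pssms["sp2"] is pssms["sp3"]  # one shared CW matrix

    def test_errors(self):
        with pytest.raises(ValueError, match="zero sites"):
            build_pssms("tf", {"sp1": []})
        with pytest.raises(ValueError, match="unequal"):
            build_pssms("tf", {"sp1": ["ACGT", "ACGTA", "ACGTA"]})


class TestScan:
    def test_background_matrix_yields_no_hits(self):
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        counts = np.tile(bg[:, None] * 1000 - 0.25, (1, 8))
        pssm = PSSM("t", counts, background=bg)
        rng = np.random.default_rng(1)
        promoter = "".join(rng.choice(list("ACGT"), 500))
        res = scan(pssm, promoter)
        assert res.hits == []
        assert np.allclose(res.all_pvalues, 1.0)

    def test_planted_consensus_recovered_at_coordinate(self, sharp_pssm):
        rng = np.random.default_rng(2)
        promoter = "".join(rng.choice(list("ACGT"), 300))
        promoter = promoter[:120] + sharp_pssm.consensus() + promoter[130:]
        res = scan(sharp_pssm, promoter)
        assert any(h.interval.start == 120 and h.strand == "+" for h in res.hits)

    def test_strand_symmetry_under_revcomp(self, sharp_pssm):
        rng = np.random.default_rng(5)
        promoter = "".join(rng.choice(list("ACGT"), 200))
        promoter = promoter[:60] + sharp_pssm.consensus() + promoter[70:]
        fwd = scan(sharp_pssm, promoter)
        rev = scan(sharp_pssm, revcomp(promoter))
        L, w = len(promoter), sharp_pssm.width
        fwd_set = {(h.interval.start, h.strand) for h in fwd.hits}
        mirrored = {
            (L - h.interval.start - w, {"+": "-", "-": "+"}[h.strand])
            for h in rev.hits
        }
        assert fwd_set == mirrored

    def test_n_bases_score_zero_and_dense_n_windows_skipped(self, sharp_pssm):
        promoter = "N" * 50 + sharp_pssm.consensus() + "N" * 50
        res = scan(sharp_pssm, promoter)
        # consensus window itself is N-free and must be found
        assert any(h.interval.start == 50 for h in res.hits)
        # windows of >20% N were skipped entirely
        assert res.n_windows < 2 * (len(promoter) - sharp_pssm.width + 1)


class TestFDR:
    def test_bh_hand_cases(self):
        assert bh_qvalues(np.array([0.01]))[0] == pytest.approx(0.01)
        np.testing.assert_allclose(
            bh_qvalues(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )
        assert (bh_qvalues(np.ones(5)) == 1.0).all()

    def test_bh_matches_textbook_step_up(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            q = bh_qvalues(p)
            # independent step-up oracle
            m = p.size
            order = np.argsort(p)
            expected = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                running = min(running, p[order[rank - 1]] * m / rank)
                expected[order[rank - 1]] = running
            np.testing.assert_allclose(q, expected, atol=1e-12)
            assert (q >= p - 1e-12).all()  # q >= p always

    def test_call_significant_family_is_species_by_motif(self, sharp_pssm):
        hit = MotifHit(
            "TF_sharp", "g1", "sp1",
            GenomicInterval("promoter", 0, 10), "+", 10.0, 1e-8, 100,
        )
        res = ScanResult("TF_sharp", "g1", "sp1", [hit], np.array([1e-8] + [0.9] * 99), 100)
        retained = call_significant([res], alpha=0.05)
        assert len(retained) == 1
        assert retained[0].q_value == pytest.approx(1e-8 * 100 / 1)


class TestConfidence:
    @pytest.mark.parametrize(
        "orgs,prov,tier,score",
        [
            ({"mouse", "human"}, None, "1a", 0.3),
            ({"mouse"}, None, "1b", 0.2),
            ({"human"}, None, "1c", 0.15),
            (set(), "CS", "2a", 0.125),
            (set(), "CW", "2b", 0.110),
            (set(), "JASPAR", "2c", 0.115),
        ],
    )
    def test_published_mapping(self, orgs, prov, tier, score):
        assert assign_confidence(orgs, prov) == (tier, score)

    def test_multiple_evidence_highest_score_wins(self):
        assert assign_confidence({"human"}, "CS") == ("1c", 0.15)
        assert assign_confidence({"mouse", "human"}, "JASPAR") == ("1a", 0.3)

    def test_unknown_inputs_rejected(self):
        with pytest.raises(ValueError):
            assign_confidence(set(), "RSAT")
        with pytest.raises(ValueError):
            assign_confidence({"zebrafish"}, None)


class TestWindowDensity:
    def _hit(self, offset):
        return MotifHit("t", "g", "s", GenomicInterval("p", 0, 10), "+", 1.0, 0.5, offset)

    def test_all_hits_in_first_bin(self):
        hits = [self._hit(50) for _ in range(7)]
        counts = window_density(hits)
        assert counts[0] == 7
        assert counts[1:].sum() == 0

    def test_distal_hit_dropped_by_retain_filter(self):
        hits = [self._hit(5001), self._hit(4999)]
        kept = retain_proximal(hits)
        assert [h.tss_offset for h in kept] == [4999]

    def test_uniform_hits_flat_profile(self):
        rng = np.random.default_rng(0)
        hits = [self._hit(int(o)) for o in rng.integers(1, 20001, 4000)]
        counts = window_density(hits)
        from scipy import stats

        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.01


class TestShuffle:
    def test_mononucleotide_counts_preserved(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 500))
        (out,) = shuffle_promoters([seq], "mononucleotide", seed=1)
        assert Counter(out) == Counter(seq)
        assert out != seq

    def test_dinucleotide_counts_preserved(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 800))
        (out,) = shuffle_promoters([seq], "dinucleotide", seed=2)
        assert Counter(zip(out, out[1:])) == Counter(zip(seq, seq[1:]))
        assert out != seq

    def test_homopolymer_and_short_inputs_unchanged(self):
        assert shuffle_promoters(["AAAAAA"], "dinucleotide", seed=0) == ["AAAAAA"]
        assert shuffle_promoters(["A"], "dinucleotide", seed=0) == ["A"]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 300))
        a = shuffle_promoters([seq], "dinucleotide", seed=7)
        b = shuffle_promoters([seq], "dinucleotide", seed=7)
        assert a == b
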