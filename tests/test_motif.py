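"""PWM scoring, exact p-values, allele windows and similarity."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from regvar.core import SequenceRecord, Variant
from regvar.motif import (
    PWM,
    Background,
    MotifScanner,
    ScanConfig,
    allele_windows,
    build_pwm_from_sites,
    log_odds,
    motif_similarity,
    reverse_complement_pwm,
    scan_window,
    score_pvalue_table,
)


def random_pwm(rng, width, motif_id="m"):
    return PWM(motif_id=motif_id, probs=rng.dirichlet(np.ones(4), size=width))


class TestBuildPwm:
    def test_point_mass_columns(self):
        pwm = build_pwm_from_sites(["ACG", "ACG"], pseudocount=0)
        assert pwm.consensus() == "ACG"
        assert np.allclose(pwm.probs.max(axis=1), 1.0)

    def test_pseudocount_hand_counted(self):
        pwm = build_pwm_from_sites(["AA", "AC"], pseudocount=0.25)
        # column 2: (A: 1.25/3, C: 1.25/3, G: .25/3, T: .25/3)
        assert np.allclose(pwm.probs[1], [1.25 / 3, 1.25 / 3, 0.25 / 3, 0.25 / 3])

    def test_ragged_sites_error(self):
        with pytest.raises(ValueError, match="unequal"):
            build_pwm_from_sites(["AC", "A"])

    def test_empty_sites_error(self):
        with pytest.raises(ValueError, match="no sites"):
            build_pwm_from_sites([])


class TestLogOdds:
    def test_background_row_scores_zero(self):
        pwm = PWM(motif_id="bgrow", probs=np.array([[0.25, 0.25, 0.25, 0.25]]))
        for pc in (0.0, 0.01, 0.5):
            lom = log_odds(pwm, ScanConfig(pseudocount_fraction=pc))
            assert np.allclose(lom.scores, 0.0)

    def test_point_mass_row_matches_formula(self):
        pwm = PWM(motif_id="pm", probs=np.array([[1.0, 0.0, 0.0, 0.0]]))
        lom = log_odds(pwm, ScanConfig(pseudocount_fraction=0.01))
        # direct evaluation of log2((p + pc*bg)/((1+pc)*bg))
        assert lom.scores[0, 0] == pytest.approx(1.9892469437031255)
        assert lom.scores[0, 1] == pytest.approx(-6.658211482751795)

    def test_zero_probability_without_pseudocount_errors(self):
        pwm = PWM(motif_id="z", probs=np.array([[1.0, 0.0, 0.0, 0.0]]))
        with pytest.raises(ValueError, match="infinite"):
            log_odds(pwm, ScanConfig(pseudocount_fraction=0.0))

    def test_integer_rounding_within_half_epsilon(self, rng):
        pwm = random_pwm(rng, 8)
        cfg = ScanConfig()
        lom = log_odds(pwm, cfg)
        assert np.all(np.abs(lom.int_scores * cfg.epsilon - lom.scores) <= cfg.epsilon / 2)


def enumerate_null(lom, bg):
    """Exhaustive 4^w enumeration with the same integer matrix."""
    w = lom.width
    dist = {}
    for word in itertools.product(range(4), repeat=w):
        s = sum(int(lom.int_scores[i, a]) for i, a in enumerate(word))
        p = math.prod(bg[a] for a in word)
        dist[s] = dist.get(s, 0.0) + p
    return dist


class TestScorePvalueTable:
    def test_single_column_point_mass(self):
        pwm = PWM(motif_id="one", probs=np.array([[0.97, 0.01, 0.01, 0.01]]))
        cfg = ScanConfig()
        lom = log_odds(pwm, cfg)
        table = score_pvalue_table(lom, cfg)
        top = int(lom.int_scores.max())
        assert table.pvalue(top) == pytest.approx(0.25)
        assert table.pvalue(table.min_score) == 1.0
        assert table.pvalue(table.max_score + 1) == 0.0

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("bg", [(0.25, 0.25, 0.25, 0.25), (0.4, 0.1, 0.1, 0.4)])
    def test_equals_exhaustive_enumeration(self, seed, bg):
        rng = np.random.default_rng(seed)
        width = int(rng.integers(1, 5))
        pwm = random_pwm(rng, width)
        cfg = ScanConfig(background=Background(bg))
        lom = log_odds(pwm, cfg)
        table = score_pvalue_table(lom, cfg)
        dist = enumerate_null(lom, bg)
        assert sum(table.pmf) == pytest.approx(1.0, abs=1e-9)
        for s in dist:
            expect = sum(p for t, p in dist.items() if t >= s)
            assert table.pvalue(s) == pytest.approx(expect, abs=1e-12)

    def test_pvalue_non_increasing(self, rng):
        pwm = random_pwm(rng, 6)
        cfg = ScanConfig()
        table = score_pvalue_table(log_odds(pwm, cfg), cfg)
        assert np.all(np.diff(table.sf) <= 1e-15)


@pytest.fixture
def long_reference(rng):
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    return SequenceRecord(name="chr1", sequence=seq)


class TestAlleleWindows:
    def test_full_windows_differ_only_at_snp(self, long_reference):
        pos = 1000
        ref_base = long_reference.sequence[pos - 1]
        alt = "A" if ref_base != "A" else "C"
        v = Variant(chrom="chr1", pos=pos, id="v", ref=ref_base, alt=alt)
        ref_win, alt_win, idx = allele_windows(v, [long_reference], ScanConfig(flank=20))
        assert len(ref_win) == 41 and idx == 20
        diffs = [i for i, (a, b) in enumerate(zip(ref_win, alt_win)) if a != b]
        assert diffs == [20]

    def test_clamped_at_sequence_start(self):
        seq = SequenceRecord(name="c", sequence="ACGTACGTACGTACGTACGTACGTACGTAC")
        v = Variant(chrom="c", pos=10, id="v", ref=seq.sequence[9], alt="T" if seq.sequence[9] != "T" else "A")
        ref_win, _, idx = allele_windows(v, [seq], ScanConfig(flank=20))
        assert ref_win == seq.sequence[:30]
        assert idx == 9

    def test_ref_mismatch_is_error(self, long_reference):
        pos = 500
        ref_base = long_reference.sequence[pos - 1]
        wrong = "G" if ref_base != "G" else "T"
        alt = next(b for b in "ACGT" if b not in (wrong,))
        v = Variant(chrom="chr1", pos=pos, id="v", ref=wrong, alt=alt)
        with pytest.raises(ValueError, match="REF mismatch"):
            allele_windows(v, [long_reference])


def sharp_pwm(consensus, q=0.94, motif_id="sharp", tf_name=""):
    probs = np.full((len(consensus), 4), (1 - q) / 3)
    for i, b in enumerate(consensus):
        probs[i, "ACGT".index(b)] = q
    return PWM(motif_id=motif_id, tf_name=tf_name, probs=probs)


class TestScanWindow:
    def setup_method(self):
        self.cfg = ScanConfig(require_snp_overlap=False)
        self.pwm = sharp_pwm("ACGTCA")
        self.lom = log_odds(self.pwm, self.cfg)
        self.table = score_pvalue_table(self.lom, self.cfg)

    def test_planted_consensus_found_at_offset(self):
        window = "TTTTTTTT" + "ACGTCA" + "TTTTTTT"
        hit = scan_window(window, self.lom, self.table, self.cfg)
        assert hit is not None and hit.start == 8 and hit.strand == "+"
        # oracle: direct scoring of that offset
        expect = sum(self.lom.int_scores[i, "ACGT".index(b)] for i, b in enumerate("ACGTCA"))
        assert hit.int_score == expect

    def test_all_n_window_has_no_hit(self):
        assert scan_window("N" * 30, self.lom, self.table, self.cfg) is None

    def test_reverse_strand_hit_mapped_to_forward(self):
        window = "TTTTTTTT" + "TGACGT" + "TTTTTTT"  # revcomp of ACGTCA
        hit = scan_window(window, self.lom, self.table, self.cfg)
        assert hit is not None and hit.strand == "-" and hit.start == 8

    def test_strand_closure(self, rng):
        from regvar.core import reverse_complement

        window = "".join(rng.choice(list("ACGT"), size=40))
        h1 = scan_window(window, self.lom, self.table, self.cfg)
        h2 = scan_window(reverse_complement(window), self.lom, self.table, self.cfg)
        s1 = h1.int_score if h1 else None
        s2 = h2.int_score if h2 else None
        assert s1 == s2

    def test_short_window_returns_none(self):
        assert scan_window("ACG", self.lom, self.table, self.cfg) is None

    def test_snp_overlap_requirement_filters_hits(self):
        cfg = ScanConfig(require_snp_overlap=True)
        window = "TTTTTTTT" + "ACGTCA" + "TTTTTTT"
        # snp at index 0: motif occurrence does not cover it
        assert scan_window(window, self.lom, self.table, cfg, snp_index=0) is None
        assert scan_window(window, self.lom, self.table, cfg, snp_index=10) is not None


class TestScanAlleles:
    def test_disrupting_allele_abolishes_hit(self):
        pwm = sharp_pwm("ACGTCA", tf_name="TF1")
        cfg = ScanConfig()
        seq = "T" * 50 + "ACGTCA" + "T" * 50
        ref = SequenceRecord(name="1", sequence=seq)
        # SNP at motif position 3 (the T), alt chosen to minimize the column prob
        v = Variant(chrom="1", pos=54, id="v", ref="T", alt="G")
        scanner = MotifScanner([pwm], cfg)
        ref_res, alt_res = scanner.scan_alleles(v, [ref])
        assert ref_res.best_hit["sharp"] is not None
        assert alt_res.best_hit["sharp"] is None

    def test_variant_far_from_motif_identical_results(self):
        pwm = sharp_pwm("ACGTCA")
        seq = "T" * 200 + "ACGTCA" + "T" * 200
        ref = SequenceRecord(name="1", sequence=seq)
        v = Variant(chrom="1", pos=100, id="v", ref="T", alt="C")
        scanner = MotifScanner([pwm], ScanConfig())
        ref_res, alt_res = scanner.scan_alleles(v, [ref])
        assert ref_res.best_hit["sharp"] is None and alt_res.best_hit["sharp"] is None

    def test_equal_probability_alleles_give_identical_hits(self):
        # column 2 splits evenly between C and G: swapping them changes nothing
        probs = np.array(
            [[0.94, 0.02, 0.02, 0.02],
             [0.02, 0.47, 0.47, 0.04],
             [0.02, 0.02, 0.02, 0.94],
             [0.94, 0.02, 0.02, 0.02],
             [0.02, 0.94, 0.02, 0.02],
             [0.02, 0.02, 0.94, 0.02]]
        )
        pwm = PWM(motif_id="eq", probs=probs)
        seq = "T" * 50 + "ACTACG" + "T" * 50
        ref = SequenceRecord(name="1", sequence=seq)
        v = Variant(chrom="1", pos=52, id="v", ref="C", alt="G")
        scanner = MotifScanner([pwm], ScanConfig(p_threshold=0.01))
        ref_res, alt_res = scanner.scan_alleles(v, [ref])
        rh, ah = ref_res.best_hit["eq"], alt_res.best_hit["eq"]
        assert rh is not None and ah is not None
        assert rh.int_score == ah.int_score and rh.start == ah.start

    def test_allele_locality(self, rng):
        """No candidate window overlaps the SNP => identical scan results."""
        pwm = sharp_pwm("ACGTCA")
        seq = "".join(rng.choice(list("ACGT"), size=400))
        ref = SequenceRecord(name="1", sequence=seq)
        cfg = ScanConfig(require_snp_overlap=True)
        scanner = MotifScanner([pwm], cfg)
        checked = 0
        for pos in range(50, 350, 13):
            base = seq[pos - 1]
            alt = "A" if base != "A" else "G"
            v = Variant(chrom="1", pos=pos, id=f"v{pos}", ref=base, alt=alt)
            ref_res, alt_res = scanner.scan_alleles(v, [ref])
            rh, ah = ref_res.best_hit["sharp"], alt_res.best_hit["sharp"]
            if rh is None and ah is None:
                checked += 1
        assert checked > 0


class TestMotifSimilarity:
    def test_self_similarity_is_one(self, rng):
        pwm = random_pwm(rng, 8)
        sim, offset, orient = motif_similarity(pwm, pwm, min_overlap=5)
        assert sim == pytest.approx(1.0)
        assert offset == 0 and orient == "+"

    def test_reverse_complement_detected(self, rng):
        pwm = sharp_pwm("ACGGTA")
        sim, offset, orient = motif_similarity(pwm, reverse_complement_pwm(pwm), min_overlap=5)
        assert sim == pytest.approx(1.0)
        assert orient == "-"

    def test_disjoint_sharp_motifs_dissimilar(self):
        a = sharp_pwm("AAAAAA", motif_id="a")
        b = sharp_pwm("CGCGCG", motif_id="b")
        sim, _, _ = motif_similarity(a, b, min_overlap=5)
        # brute-force oracle over offsets/orientations
        best = -2.0
        for orient_probs in (b.probs, reverse_complement_pwm(b).probs):
            for off in range(-1, 2):
                lo, hi = max(0, off), min(6, off + 6)
                cols = []
                for i in range(lo, hi):
                    x, y = a.probs[i], orient_probs[i - off]
                    x, y = x - x.mean(), y - y.mean()
                    cols.append(float(x @ y / np.sqrt((x @ x) * (y @ y))))
                best = max(best, float(np.mean(cols)))
        assert sim == pytest.approx(best, abs=1e-12)
        assert sim < 0.75

    def test_min_overlap_larger_than_widths_errors(self, rng):
        with pytest.raises(ValueError, match="min_overlap"):
            motif_similarity(random_pwm(rng, 4), random_pwm(rng, 4), min_overlap=5)


@given(st.integers(0, 10_000))
def test_tightening_threshold_never_adds_hits(seed):
    rng = np.random.default_rng(seed)
    pwm = PWM(motif_id="m", probs=rng.dirichlet(np.ones(4) * 0.3, size=5))
    window = "".join(rng.choice(list("ACGT"), size=30))
    hits = {}
    for thr in (0.05, 0.01, 0.001):
        cfg = ScanConfig(p_threshold=thr, require_snp_overlap=False)
        lom = log_odds(pwm, cfg)
        table = score_pvalue_table(lom, cfg)
        hits[thr] = scan_window(window, lom, table, cfg)
    if hits[0.001] is not None:
        assert hits[0.01] is not None
    if hits[0.01] is not None:
        assert hits[0.05] is not None
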