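"""Shape profiles, Δshape, context-matched ΔMGW and the A-tract tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from sklearn.base import clone

from methylshape.alphabet import AlphabetError, methylate, reverse_complement
from methylshape.predict import (
    ATRACT_3BP_SERIES,
    PentamerShapeModel,
    atract_analysis,
    collect_paired_mgw,
    delta_mgw_context_matched,
    delta_shape,
    shape_profile,
)
from methylshape.tableset import build_context_table, build_table, HEXAMER_CG
from methylshape.synth import (
    FragmentDesign,
    TruthModel,
    design_pool,
    simulate_paired_records,
    simulate_records,
)
from conftest import methyl_seqs


class TestProfile:
    def test_defined_entry_counts(self, mpqt):
        rng = np.random.default_rng(0)
        for n in range(5, 21):
            seq = "".join(rng.choice(list("ACGT"), size=n))
            prof = shape_profile(seq, mpqt)
            assert np.isfinite(prof.mgw).sum() == n - 4
            assert np.isfinite(prof.prot).sum() == n - 4
            assert np.isfinite(prof.roll).sum() == n - 3
            assert np.isfinite(prof.helt).sum() == n - 3

    def test_length5_single_window(self, mpqt):
        prof = shape_profile("AACGT", mpqt)
        ft = mpqt.query("AACGT")
        assert prof.mgw[2] == ft.mgw and np.isfinite(prof.mgw).sum() == 1
        # both defined steps fall back to the single window's slots
        assert prof.roll[1] == ft.roll23 and prof.roll[2] == ft.roll34

    def test_uniform_table_constant_profile(self, uniform_table):
        prof = shape_profile("ACGTAmgTTACG", uniform_table)
        assert np.all(prof.mgw[np.isfinite(prof.mgw)] == 5.0)
        assert np.all(prof.roll[np.isfinite(prof.roll)] == 1.0)

    def test_interior_step_two_term_average(self, mpqt):
        seq = "ACGTTmgA"
        prof = shape_profile(seq, mpqt)
        # step between bp 3 and 4 (0-based): windows centered at 3 and 4
        want = 0.5 * (mpqt.query(seq[1:6]).roll34 + mpqt.query(seq[2:7]).roll23)
        assert prof.roll[3] == pytest.approx(want)
        want_h = 0.5 * (mpqt.query(seq[1:6]).helt34 + mpqt.query(seq[2:7]).helt23)
        assert prof.helt[3] == pytest.approx(want_h)

    def test_step_policy_flag(self, mpqt):
        seq = "ACGTTACA"
        pl = shape_profile(seq, mpqt, step_policy="left")
        pr = shape_profile(seq, mpqt, step_policy="right")
        assert pl.roll[3] == mpqt.query(seq[1:6]).roll34
        assert pr.roll[3] == mpqt.query(seq[2:7]).roll23

    def test_too_short_raises(self, mpqt):
        with pytest.raises(AlphabetError):
            shape_profile("ACGT", mpqt)

    @settings(max_examples=150, derandomize=True)
    @given(methyl_seqs(min_size=5, max_size=25))
    def test_strand_symmetry(self, mpqt, seq):
        fwd = shape_profile(seq, mpqt)
        rev = shape_profile(reverse_complement(seq), mpqt)
        np.testing.assert_allclose(rev.mgw, fwd.mgw[::-1], atol=1e-12)
        np.testing.assert_allclose(rev.prot, fwd.prot[::-1], atol=1e-12)
        np.testing.assert_allclose(rev.roll, fwd.roll[::-1], atol=1e-12)
        np.testing.assert_allclose(rev.helt, fwd.helt[::-1], atol=1e-12)


class TestDelta:
    def test_empty_spec_is_zero(self, pqt, mpqt):
        d = delta_shape("ACGTTACAGT", [], pqt, mpqt)
        assert np.nansum(np.abs(d.mgw)) == 0 and np.nansum(np.abs(d.roll)) == 0
        assert np.isfinite(d.mgw).sum() == 10 - 4

    def test_single_window_reproduces_table_difference(self, pqt, mpqt):
        d = delta_shape("AACGT", "all_cpg", pqt, mpqt)
        assert d.mgw[2] == pytest.approx(
            mpqt.query("AAmgT").mgw - pqt.query("AACGT").mgw
        )

    def test_planted_roll_shift_at_mg_step(self, truth, pqt, mpqt):
        seq = "TTAACGTTAA"
        d = delta_shape(seq, "all_cpg", pqt, mpqt)
        # the mg step sits at step (4,5); its Δ averages two window slots,
        # both planted near the configured +6° shift
        assert d.roll[4] == pytest.approx(truth.roll_shift, abs=3 * truth.effect_sd)


class TestContextMatchedDelta:
    @pytest.fixture(scope="class")
    def setup(self):
        # controlled pool: fixed left context, all four bases after AAAAC
        truth = TruthModel(seed=13, pos6_mgw=0.4)
        designs_u = [
            FragmentDesign(f"u{b}", core="AAAAC" + b, left_flank="ATTA")
            for b in "ACGT"
        ]
        design_m = [FragmentDesign("m", core="AAAAmg", left_flank="ATTA")]
        unmeth = simulate_records(truth, designs_u, sigma=0.0, seed=0)
        meth = simulate_records(truth, design_m, sigma=0.0, seed=0)
        pqt = build_table(unmeth, margin=1)
        mpqt = build_table(meth, margin=1)
        hexa = build_context_table(unmeth, HEXAMER_CG, margin=1)
        return truth, unmeth[0].seq.replace("AAAACA", "AAAACG"), pqt, mpqt, hexa

    def test_recovers_planted_delta_exactly(self, setup):
        truth, _, pqt, mpqt, hexa = setup
        seq = "ATTA" + "AAAACG" + "TAAT"
        planted = truth.pentamer_mgw["AAAAm"] - truth.pentamer_mgw["AAAAC"]
        got = delta_mgw_context_matched(seq, 6, [8], pqt, mpqt, hexa)
        assert got == pytest.approx(planted, abs=1e-10)

    def test_plain_pqt_estimate_is_biased(self, setup):
        truth, _, pqt, mpqt, hexa = setup
        seq = "ATTA" + "AAAACG" + "TAAT"
        planted = truth.pentamer_mgw["AAAAm"] - truth.pentamer_mgw["AAAAC"]
        plain = mpqt.query(methylate(seq)[4:9]).mgw - pqt.query(seq[4:9]).mgw
        # the pentamer table averages the out-of-window base: bias 3η/4
        assert plain - planted == pytest.approx(0.75 * truth.pos6_mgw, abs=1e-10)

    def test_full_cpg_inside_window_equals_plain_delta(self, pqt, mpqt):
        seq = "TTAACGTTAA"  # CpG at (4, 5), fully inside the window of bp 4
        d = delta_shape(seq, [4], pqt, mpqt)
        got = delta_mgw_context_matched(seq, 4, [4], pqt, mpqt)
        assert got == pytest.approx(d.mgw[4])

    def test_pbxhox_offsets_share_hexamer_context(self):
        # a CpG at offset 6/7 contributes only its C to the pentamer window
        # of A4 (site[1:6], 0-based), and a CpG at 10/11 only its C to the
        # window of A8 (site[5:10]); both imply an NNAYCG hexamer context,
        # and with matching NNAY letters the two contexts coincide
        site67 = "ATGATCGATTAA"  # CG at 1-based 6/7
        site1011 = "ATGATTAATCGA"  # CG at 1-based 10/11
        hex_a4 = site67[1:7]
        hex_a8 = site1011[5:11]
        assert hex_a4.endswith("CG") and hex_a8.endswith("CG")
        # the confounded base (position 6 of each hexamer context) lies one
        # past the pentamer window in both cases
        assert site67[1:6] == hex_a4[:5] and site1011[5:10] == hex_a8[:5]


class TestATract:
    def _paired_pools(self, mgw_shift, seed=0, sigma=0.1, n_occ=20):
        truth = TruthModel(seed=seed, mgw_shift=mgw_shift, effect_sd=0.0, sigma=sigma)
        designs = [
            FragmentDesign(f"d_{ctx}", core=methylate(ctx), left_flank="ATTA")
            for ctx in ATRACT_3BP_SERIES
        ]
        return simulate_paired_records(truth, designs, n_occ=n_occ, seed=seed + 1)

    def test_planted_narrowing_detected(self):
        unmeth, meth = self._paired_pools(mgw_shift=-0.5)
        paired = {
            ctx: collect_paired_mgw(unmeth, meth, ctx) for ctx in ATRACT_3BP_SERIES
        }
        res = atract_analysis(paired, test="wilcoxon")
        assert (res["p_value"] <= 0.01).all()
        assert set(res["stars"]) <= {"**", "***"}
        res_t = atract_analysis(paired, test="ttest")
        assert (res_t["p_value"] <= 0.01).all()

    def test_planted_widening_not_significant(self):
        unmeth, meth = self._paired_pools(mgw_shift=+0.5)
        paired = {"AAACG": collect_paired_mgw(unmeth, meth, "AAACG")}
        res = atract_analysis(paired, test="wilcoxon")
        assert res["p_value"].iloc[0] >= 0.95

    def test_identical_samples_give_p_one(self):
        unmeth, _ = self._paired_pools(mgw_shift=-0.5)
        paired = {"AAACG": collect_paired_mgw(unmeth, unmeth, "AAACG")}
        res = atract_analysis(paired)
        assert res["p_value"].iloc[0] == 1.0 and res["stars"].iloc[0] == ""

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            atract_analysis({"AAACG": (np.array([5.0]), np.array([4.5]))})


class TestEstimator:
    def test_fit_transform_round_trip(self, truth):
        designs = design_pool("unmethylated", coverage=1)
        recs = simulate_records(truth, designs, sigma=0.0, seed=3)
        model = PentamerShapeModel(universe="unmethylated").fit(recs)
        assert model.n_keys_ == 512
        (prof,) = model.transform(["ACGTACGTA"])
        np.testing.assert_allclose(
            prof.mgw[2:7],
            [truth.bp_truth("ACGTACGTA"[c - 2 : c + 3])[0] for c in range(2, 7)],
            atol=1e-10,
        )

    def test_sklearn_protocol(self):
        model = PentamerShapeModel(margin=2, step_policy="left")
        params = model.get_params()
        assert params["margin"] == 2
        cloned = clone(model)
        assert cloned.get_params() == params
        with pytest.raises(RuntimeError):
            cloned.transform(["ACGTA"])
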