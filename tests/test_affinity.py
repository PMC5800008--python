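"""Cleavage energetics, elastic-net fitting and the Pbx-Hox comparator."""

import numpy as np
import pandas as pd
import pytest

from methylshape.affinity import (
    ShapeAffinityRegressor,
    classify_cpg_offset,
    counts_to_energy,
    delta_features,
    feature_layout,
    featurize_kmer,
    filter_hexamers,
    fit_affinity_model,
    methylation_effect,
    predict_dddG,
)


def _cleavage(counts, variant="unmethylated"):
    hexamers = ["AAAAAA", "AAAAAC", "AAAAAG", "AAAAAT"][: len(counts)]
    return pd.DataFrame(
        {
            "hexamer": hexamers,
            "variant": variant,
            "cpg_start": pd.NA,
            "count": counts,
        }
    )


class TestEnergetics:
    def test_count_threshold(self):
        out = filter_hexamers(_cleavage([24, 25, 26]), min_count=25)
        assert sorted(out["count"]) == [25, 26]

    def test_min_count_zero_is_identity(self):
        df = _cleavage([1, 2, 3])
        assert filter_hexamers(df, min_count=0).equals(df)

    def test_all_below_threshold_warns(self):
        with pytest.warns(UserWarning):
            out = filter_hexamers(_cleavage([1, 2]), min_count=25)
        assert out.empty

    def test_equal_counts_give_zero_energy(self):
        out = counts_to_energy(_cleavage([40, 40, 40]))
        np.testing.assert_allclose(out["ddG"], 0.0)

    def test_closed_form(self):
        # one count at e times the class mean -> energy exactly -1
        mean = 100.0
        c = np.e * mean
        rest = (3 * mean - c) / 2  # two fillers keeping the class mean
        out = counts_to_energy(_cleavage([c, rest, rest]))
        assert out.loc[0, "ddG"] == pytest.approx(-1.0)

    def test_scale_invariance(self):
        df = _cleavage([30, 60, 90])
        e1 = counts_to_energy(df)["ddG"]
        df2 = df.assign(count=df["count"] * 2)
        e2 = counts_to_energy(df2)["ddG"]
        np.testing.assert_allclose(e1, e2)

    def test_reference_hexamer(self):
        df = _cleavage([30, 60])
        out = counts_to_energy(df, reference="AAAAAA")
        assert out.loc[0, "ddG"] == pytest.approx(0.0)
        assert out.loc[1, "ddG"] == pytest.approx(-np.log(2))

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            counts_to_energy(_cleavage([0, 10]))


class TestFeaturization:
    def test_hexamer_layout_is_22(self, pqt):
        vec = featurize_kmer("ACGTAC", pqt)
        assert vec.shape == (22,)
        assert len(feature_layout(6)) == 22

    def test_wildcard_padding_matches_brute_force(self, pqt):
        h = "ACGTAC"
        vec = featurize_kmer(h, pqt)
        # MGW at position 0: pentamer centered there needs two left flanks
        want = np.mean(
            [pqt.query(a + b + h[:3]).mgw for a in "ACGT" for b in "ACGT"]
        )
        assert vec[0] == pytest.approx(want)

    def test_methylated_kmer(self, mpqt):
        vec = featurize_kmer("ACGmgC", mpqt)
        assert np.all(np.isfinite(vec))

    def test_delta_features_zero_without_marks(self, pqt, mpqt):
        d = delta_features("ACTTAC", [], pqt, mpqt)
        # same letters queried on tables that agree on unmethylated keys
        np.testing.assert_allclose(d, 0.0, atol=1e-12)


class TestElasticNet:
    def _data(self, n=60, p=8, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        w = rng.normal(size=p)
        y = X @ w + 0.5 + noise * rng.normal(size=n)
        return X, y, w

    def test_unpenalized_matches_normal_equations(self):
        X, y, _ = self._data()
        model = fit_affinity_model(X, y, l1=0.0, l2=0.0)
        Xa = np.column_stack([X, np.ones(len(y))])
        beta = np.linalg.lstsq(Xa, y, rcond=None)[0]
        np.testing.assert_allclose(model.coef_, beta[:-1], atol=1e-8)
        assert model.intercept_ == pytest.approx(beta[-1], abs=1e-8)

    def test_ridge_matches_closed_form(self):
        X, y, _ = self._data()
        l2 = 3.0
        model = fit_affinity_model(X, y, l1=0.0, l2=l2)
        mu, sd = X.mean(0), X.std(0)
        Xs = (X - mu) / sd
        w = np.linalg.solve(Xs.T @ Xs + l2 * np.eye(X.shape[1]), Xs.T @ (y - y.mean()))
        np.testing.assert_allclose(model.coef_, w / sd, atol=1e-10)

    def test_large_l1_shrinks_to_intercept(self):
        X, y, _ = self._data()
        model = fit_affinity_model(X, y, l1=1e6, l2=0.0)
        np.testing.assert_allclose(model.coef_, 0.0, atol=1e-10)
        assert model.intercept_ == pytest.approx(y.mean())

    def test_planted_recovery(self):
        X, y, w = self._data(n=200, p=10, seed=1, noise=0.05)
        model = fit_affinity_model(X, y, l1=1e-3, l2=1e-3)
        assert np.all(np.sign(model.coef_) == np.sign(w))
        rel = np.linalg.norm(model.coef_ - w) / np.linalg.norm(w)
        assert rel <= 0.10

    def test_delta_prediction_is_linear(self):
        X, y, _ = self._data()
        model = fit_affinity_model(X, y, l1=0.02, l2=0.01)
        fm, fu = X[0], X[1]
        assert model.predict_delta(fm - fu) == pytest.approx(
            float(model.predict(fm[None])[0] - model.predict(fu[None])[0])
        )
        assert predict_dddG(model, np.zeros(X.shape[1])) == 0.0

    def test_zero_variance_feature_dropped(self):
        X, y, _ = self._data()
        X[:, 3] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_affinity_model(X, y, l1=0.0, l2=0.0)
        assert model.coef_[3] == 0.0

    def test_layout_mismatch_raises(self):
        X, y, _ = self._data()
        model = fit_affinity_model(X, y)
        with pytest.raises(ValueError, match="layout"):
            model.predict_delta(np.zeros(5))

    def test_feature_subset_model(self, pqt):
        hexamers = ["ACGTAC", "TTGACA", "GGATCC", "AATTCG", "CATGCA", "TGCAGT"]
        X = np.vstack([featurize_kmer(h, pqt) for h in hexamers])
        y = np.arange(len(hexamers), dtype=float)
        model = ShapeAffinityRegressor(l1=0.0, l2=0.1, feature_names=["Roll"]).fit(X, y)
        layout = feature_layout(6)
        for i, (feat, _) in enumerate(layout):
            if feat != "Roll":
                assert model.coef_[i] == 0.0

    def test_text_round_trip(self):
        X, y, _ = self._data(p=22)
        model = fit_affinity_model(X, y, l1=0.01, l2=0.02)
        back = ShapeAffinityRegressor.from_text(model.to_text())
        np.testing.assert_allclose(back.coef_, model.coef_)
        assert back.intercept_ == pytest.approx(model.intercept_)


class TestPbxHox:
    def test_printed_pattern_mappings(self):
        assert classify_cpg_offset("ATGATCGATAAA", 6) == "6/7"
        assert classify_cpg_offset("ATGATTAACGAA", 9) == "9/10"
        assert classify_cpg_offset("ATGATTAATCGA", 10) == "10/11"
        assert classify_cpg_offset("ATGATTAACGAA", None) == "none"

    def test_other_offset(self):
        assert classify_cpg_offset("ATGACGAATAAA", 5) == "other"

    def test_pattern_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            classify_cpg_offset("AAAAAAAAAAAA", 6)

    def test_non_cpg_position_rejected(self):
        with pytest.raises(ValueError, match="not CpG"):
            classify_cpg_offset("ATGATCGATAAA", 3)

    def test_equal_affinities_give_zero(self):
        df = pd.DataFrame(
            {
                "site": ["ATGATCGATAAA"] * 2,
                "cpg_start": [pd.NA, 6],
                "affinity": [1.3, 1.3],
            }
        )
        out = methylation_effect(df)
        assert out["dddG"].iloc[0] == pytest.approx(0.0)
        assert out["offset_class"].iloc[0] == "6/7"

    def test_tenfold_gain_is_minus_ln10(self):
        df = pd.DataFrame(
            {
                "site": ["ATGATTAACGAA"] * 2,
                "cpg_start": [pd.NA, 9],
                "affinity": [0.2, 2.0],
            }
        )
        out = methylation_effect(df)
        assert out["dddG"].iloc[0] == pytest.approx(-np.log(10))

    def test_unpaired_and_nonpositive_rejected(self):
        df = pd.DataFrame(
            {"site": ["ATGATCGATAAA"], "cpg_start": [6], "affinity": [1.0]}
        )
        with pytest.raises(ValueError, match="unmethylated partner"):
            methylation_effect(df)
        df2 = pd.DataFrame(
            {
                "site": ["ATGATCGATAAA"] * 2,
                "cpg_start": [pd.NA, 6],
                "affinity": [1.0, -1.0],
            }
        )
        with pytest.raises(ValueError, match="positive"):
            methylation_effect(df2)
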