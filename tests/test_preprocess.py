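"""Mental-health scoring, predictor assembly, normalization/residualization."""

import numpy as np
import pytest

from resilnet.preprocess import (
    assemble_predictors,
    score_mental_health,
    standardize_and_residualize,
)
from resilnet.synthetic import BSI_SUBSCALE_MAP


def _bsi_with(subscale, value, fill=1):
    bsi = np.full((3, 18), fill)
    bsi[:, list(BSI_SUBSCALE_MAP[subscale])] = value
    return bsi


class TestScoreMentalHealth:
    def test_who5_maximum(self):
        who5 = np.full((3, 5), 5)
        s = score_mental_health(who5, np.full((3, 18), 1))
        assert (s.who5_sum == 25).all()

    def test_bsi_inversion_of_minimum(self):
        # depression items all 1 -> raw sum 6 (range 6..30) -> inverted 30
        s = score_mental_health(np.zeros((3, 5), int),
                                _bsi_with("depression", 1))
        assert (s.bsi_dep_inv == 30).all()

    def test_bsi_midpoint_fixed_point(self):
        # anxiety items all 3 -> raw 18 -> inversion leaves the midpoint
        s = score_mental_health(np.zeros((3, 5), int),
                                _bsi_with("anxiety", 3))
        assert (s.bsi_anx_inv == 18).all()

    def test_inversion_is_involution(self):
        rng = np.random.default_rng(1)
        bsi = rng.integers(1, 6, size=(20, 18))
        s = score_mental_health(np.zeros((20, 5), int), bsi)
        raw_som = bsi[:, list(BSI_SUBSCALE_MAP["somatization"])].sum(axis=1)
        assert np.array_equal(36 - s.bsi_som_inv, raw_som)

    def test_out_of_range_names_position(self):
        who5 = np.zeros((3, 5), int)
        who5[1, 2] = 9
        with pytest.raises(ValueError, match=r"who5\[1, 2\]"):
            score_mental_health(who5, np.full((3, 18), 1))

    def test_bad_subscale_map_rejected(self):
        bad = {"somatization": range(6), "depression": range(6),
               "anxiety": range(6, 12)}
        with pytest.raises(ValueError, match="partition"):
            score_mental_health(np.zeros((2, 5), int), np.full((2, 18), 1),
                                subscale_map=bad)


class TestAssemblePredictors:
    def test_negative_codes_become_zero(self):
        dh_sev = np.zeros((2, 3))
        dh_sev[0, 1] = -1
        X, _ = assemble_predictors(np.zeros((2, 3)), dh_sev, np.zeros((2, 2)))
        assert X[0, 4] == 0.0
        assert (X >= 0).all()

    def test_default_column_count(self):
        X, names = assemble_predictors(
            np.zeros((4, 58)), np.zeros((4, 58)), np.zeros((4, 27))
        )
        assert X.shape[1] == 143 and len(names) == 143
        assert names[0] == "DHf01" and names[58] == "DHs01"
        assert names[-1] == "LE27"

    def test_identity_on_valid_data_and_idempotent(self):
        rng = np.random.default_rng(0)
        blocks = (rng.integers(0, 8, (5, 58)), rng.integers(0, 6, (5, 58)),
                  rng.integers(0, 6, (5, 27)))
        X1, _ = assemble_predictors(*blocks)
        X2, _ = assemble_predictors(X1[:, :58], X1[:, 58:116], X1[:, 116:])
        assert np.array_equal(X1, X2)

    def test_mismatched_subjects(self):
        with pytest.raises(ValueError, match="subject"):
            assemble_predictors(np.zeros((3, 58)), np.zeros((4, 58)),
                                np.zeros((3, 27)))


class TestStandardizeResidualize:
    def test_annihilates_covariate(self):
        rng = np.random.default_rng(2)
        age = rng.normal(22, 4, 300)
        gender = rng.integers(0, 2, 300)
        Y = (2 * age)[:, None]
        out, _ = standardize_and_residualize(Y, age, gender)
        assert abs(np.corrcoef(out[:, 0], age)[0, 1]) < 1e-8
        assert out[:, 0].mean() == pytest.approx(0, abs=1e-10)
        assert out[:, 0].std() == pytest.approx(1, abs=1e-10)

    def test_near_identity_on_clean_normal_column(self):
        rng = np.random.default_rng(3)
        n = 1000
        age = rng.normal(22, 4, n)
        gender = rng.integers(0, 2, n)
        y = rng.normal(size=n)
        out, _ = standardize_and_residualize(y[:, None], age, gender)
        assert np.corrcoef(out[:, 0], y)[0, 1] > 0.99

    def test_ties_handled(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 4, 120).astype(float)    # many ties
        age = rng.normal(22, 4, 120)
        gender = rng.integers(0, 2, 120)
        out, _ = standardize_and_residualize(y[:, None], age, gender)
        assert out[:, 0].mean() == pytest.approx(0, abs=1e-10)
        assert out[:, 0].std() == pytest.approx(1, abs=1e-10)

    def test_constant_column_errors(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_and_residualize(np.ones((10, 1)), np.arange(10.0),
                                        np.zeros(10))

    def test_nonbinary_gender_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            standardize_and_residualize(np.random.default_rng(0).normal(size=(10, 1)),
                                        np.arange(10.0), np.full(10, 2))

    def test_orthogonal_column_unchanged_up_to_scale(self):
        rng = np.random.default_rng(5)
        n = 500
        age = rng.normal(size=n)
        gender = rng.integers(0, 2, n)
        y = rng.normal(size=n)
        # orthogonalize y against covariates exactly
        C = np.column_stack([np.ones(n), age, gender])
        y = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
        out, _ = standardize_and_residualize(y[:, None], age, gender,
                                             normalize="none")
        r = np.corrcoef(out[:, 0], y)[0, 1]
        assert r > 1 - 1e-12


def test_design_invariants(small_cohort, small_design):
    d = small_design
    n = small_cohort.n_subjects
    assert d.Y.shape == (n, 4) and d.X.shape == (n, 143)
    assert np.abs(d.Y.mean(axis=0)).max() < 1e-8
    assert np.abs(d.Y.var(axis=0) - 1).max() < 1e-8
    assert (d.X >= 0).all()
    for j in range(4):
        assert abs(np.corrcoef(d.Y[:, j], small_cohort.age)[0, 1]) < 1e-8
        assert abs(np.corrcoef(d.Y[:, j], small_cohort.gender)[0, 1]) < 1e-8
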