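"""Top-τ masks, coverage/focus metrics, derived features, XAI table."""

import numpy as np
import pandas as pd
import pytest

from lesionfocus.xai import (AttributionCase, PresentOnlyViolation,
                             build_xai_table, center_of_mass_distance,
                             coverage_metrics, derived_features,
                             leakage_from_precision, top_tau_mask)


class TestTopTauMask:
    def test_selects_k_largest_of_distinct_values(self, rng):
        values = rng.permutation(20).astype(float).reshape(4, 5)
        domain = np.ones((4, 5), bool)
        top = top_tau_mask(values, 20, domain)
        assert top.k == 4
        assert set(values[top.mask]) == {16.0, 17.0, 18.0, 19.0}

    def test_tau_ten_of_ten_pixel_domain_is_one_pixel(self, rng):
        domain = np.zeros((5, 5), bool)
        domain.ravel()[:10] = True
        top = top_tau_mask(rng.uniform(size=(5, 5)), 10, domain)
        assert top.k == 1 and top.mask.sum() == 1

    def test_round_half_away_from_zero(self):
        domain = np.zeros((5, 5), bool)
        domain.ravel()[:10] = True  # 5% of 10 = 0.5 -> k = 1
        top = top_tau_mask(np.arange(25.0).reshape(5, 5), 5, domain)
        assert top.k == 1

    def test_empty_selection_marker(self):
        domain = np.zeros((5, 5), bool)
        domain[0, 0] = True  # 5% of 1 = 0.05 -> k = 0
        top = top_tau_mask(np.ones((5, 5)), 5, domain)
        assert top.is_empty and not top.mask.any()

    def test_ties_broken_row_major(self):
        domain = np.ones((3, 3), bool)
        top = top_tau_mask(np.zeros((3, 3)), 33.4, domain)  # k = 3, all tied
        assert top.mask.ravel()[:3].all() and not top.mask.ravel()[3:].any()

    def test_nestedness_across_tau(self, rng):
        for _ in range(100):
            values = rng.normal(size=(16, 16))
            domain = rng.uniform(size=(16, 16)) < 0.7
            if not domain.any():
                continue
            m10 = top_tau_mask(values, 10, domain).mask
            m20 = top_tau_mask(values, 20, domain).mask
            assert (m10 <= m20).all()

    def test_mask_confined_to_domain(self, rng):
        domain = rng.uniform(size=(8, 8)) < 0.5
        domain[0, 0] = True
        top = top_tau_mask(rng.normal(size=(8, 8)), 20, domain)
        assert (top.mask <= domain).all()


class TestCoverageMetrics:
    @staticmethod
    def _case(n_top, n_lesion, n_inter, shape=(10, 10)):
        top_mask = np.zeros(shape, bool)
        lesion = np.zeros(shape, bool)
        top_mask.ravel()[:n_top] = True
        lesion.ravel()[n_top - n_inter : n_top - n_inter + n_lesion] = True
        from lesionfocus.xai import TopTauMask

        return TopTauMask(top_mask, 20, n_top, shape[0] * shape[1]), lesion

    def test_pixel_enumeration_example(self):
        top, lesion = self._case(n_top=10, n_lesion=8, n_inter=4)
        cov = coverage_metrics(top, lesion)
        assert cov["APIL"] == pytest.approx(0.4)
        assert cov["ARIL"] == pytest.approx(0.5)
        assert cov["Dice"] == pytest.approx(2 * 4 / 18, abs=5e-5)
        assert cov["Leak"] == pytest.approx(0.6)

    def test_subset_gives_perfect_precision(self):
        top, lesion = self._case(n_top=5, n_lesion=8, n_inter=5)
        cov = coverage_metrics(top, lesion)
        assert cov["APIL"] == 1.0 and cov["Leak"] == 0.0

    def test_leakage_complements_published_precision(self):
        # representative retina-dominant GT cyst case
        assert leakage_from_precision(0.102) == pytest.approx(0.898)

    def test_empty_lesion_raises(self):
        top, _ = self._case(5, 8, 2)
        with pytest.raises(PresentOnlyViolation):
            coverage_metrics(top, np.zeros((10, 10), bool))

    def test_empty_top_mask_is_undefined(self):
        from lesionfocus.xai import TopTauMask

        top = TopTauMask(np.zeros((4, 4), bool), 5, 0, 16)
        lesion = np.zeros((4, 4), bool)
        lesion[0, 0] = True
        assert np.isnan(coverage_metrics(top, lesion)["APIL"])


class TestCenterOfMass:
    def test_mass_on_lesion_gives_zero(self):
        lesion = np.zeros((9, 9), bool)
        lesion[3:6, 3:6] = True
        heat = lesion.astype(float)
        assert center_of_mass_distance(heat, lesion) == pytest.approx(0.0)

    def test_three_four_five_triangle(self):
        lesion = np.zeros((8, 8), bool)
        lesion[3, 4] = True
        heat = np.zeros((8, 8))
        heat[0, 0] = 1.0
        assert center_of_mass_distance(heat, lesion) == pytest.approx(5.0)

    def test_translation_equivariance(self, rng):
        heat = np.zeros((20, 20))
        heat[2:6, 2:6] = rng.uniform(size=(4, 4))
        lesion = np.zeros((20, 20), bool)
        lesion[4:8, 5:9] = True
        d0 = center_of_mass_distance(heat, lesion)
        d1 = center_of_mass_distance(np.roll(heat, (2, 7), axis=(0, 1)),
                                     np.roll(lesion, (2, 7), axis=(0, 1)))
        assert d0 == pytest.approx(d1, abs=1e-9)

    def test_zero_mass_is_undefined(self):
        lesion = np.zeros((5, 5), bool)
        lesion[1, 1] = True
        assert np.isnan(center_of_mass_distance(np.zeros((5, 5)), lesion))


class TestDerivedFeatures:
    def test_ncom_and_focus_proximity(self):
        out = derived_features(com_dist=5.0, lesion_pixels=100, apil5=0.2,
                               apil20=0.1, pam=3.0)
        assert out["nCOM"] == pytest.approx(0.5)
        assert out["FP"] == pytest.approx(-0.5)
        assert out["FC"] == pytest.approx(2.0)
        assert out["LP"] == 100

    def test_focus_concentration_definition(self):
        # |A5∩L| = |A20∩L| = 2 with |A5| = 5, |A20| = 20 -> FC = 0.4/0.1 = 4
        out = derived_features(1.0, 10, apil5=2 / 5, apil20=2 / 20, pam=1.0)
        assert out["FC"] == pytest.approx(4.0)

    def test_fully_contained_masks_give_unit_fc(self):
        out = derived_features(1.0, 50, apil5=1.0, apil20=1.0, pam=1.0)
        assert out["FC"] == pytest.approx(1.0)

    def test_zero_apil20_leaves_fc_undefined(self):
        out = derived_features(1.0, 10, apil5=0.0, apil20=0.0, pam=1.0)
        assert np.isnan(out["FC"])


def _naive_metrics(values, domain, lesion, tau):
    """Independent per-pixel enumeration oracle."""
    idx = [i for i in range(values.size) if domain.ravel()[i]]
    order = sorted(idx, key=lambda i: (-values.ravel()[i], i))
    k = int(np.floor(tau / 100 * len(idx) + 0.5))
    selected = set(order[:k])
    lesion_set = {i for i in range(values.size) if lesion.ravel()[i]}
    inter = len(selected & lesion_set)
    if k == 0:
        return None
    return {
        "APIL": inter / k,
        "ARIL": inter / len(lesion_set),
        "Dice": 2 * inter / (k + len(lesion_set)),
        "Leak": 1 - inter / k,
    }


class TestOracleEquivalence:
    def test_matches_naive_enumeration(self, rng):
        for _ in range(50):
            values = rng.normal(size=(32, 32))
            values[rng.uniform(size=(32, 32)) < 0.3] = 0.0  # force ties
            domain = rng.uniform(size=(32, 32)) < 0.6
            lesion = (rng.uniform(size=(32, 32)) < 0.1) & domain
            if not domain.any() or not lesion.any():
                continue
            for tau in (5, 10, 20):
                expected = _naive_metrics(values, domain, lesion, tau)
                got = coverage_metrics(top_tau_mask(values, tau, domain),
                                       lesion)
                if expected is None:
                    assert np.isnan(got["APIL"])
                    continue
                for key, val in expected.items():
                    assert got[key] == pytest.approx(val, abs=1e-12)


class TestXaiTable:
    @staticmethod
    def _cases(rng, n=6, mode="gt"):
        cases = []
        for i in range(n):
            heat = rng.uniform(size=(16, 16))
            lesion = np.zeros((16, 16), bool)
            lesion[2:6, 2 + i : 6 + i] = True
            domain = np.ones((16, 16), bool)
            cases.append(AttributionCase(
                slice_id=f"s{i}", lesion_class="hole", mode=mode,
                processed=heat, lesion_mask=lesion, domain_mask=domain))
        return cases

    def test_row_per_present_lesion_and_columns(self, rng):
        cases = self._cases(rng, 6)
        empty = AttributionCase("s9", "cyst", "gt",
                                np.ones((16, 16)),
                                np.zeros((16, 16), bool),
                                np.ones((16, 16), bool))
        table = build_xai_table(cases + [empty])
        assert len(table) == 6  # present-only: the empty-lesion case dropped
        for col in ("APIL20", "ARIL10", "Dice5", "Leak20", "COM_dist",
                    "nCOM", "FP", "FC", "PAM", "LP"):
            assert col in table.columns

    def test_identities_hold_on_every_record(self, rng):
        table = build_xai_table(self._cases(rng, 8))
        for tau in (5, 10, 20):
            np.testing.assert_allclose(
                table[f"APIL{tau}"] + table[f"Leak{tau}"], 1.0, atol=1e-12)
            # Dice harmonic identity wherever the intersection is non-empty
            apil, aril, dice = (table[f"APIL{tau}"], table[f"ARIL{tau}"],
                                table[f"Dice{tau}"])
            nonzero = apil > 0
            np.testing.assert_allclose(
                (dice * (apil + aril))[nonzero],
                (2 * apil * aril)[nonzero], rtol=1e-9)
        assert (table["ARIL5"] <= table["ARIL10"] + 1e-12).all()
        assert (table["ARIL10"] <= table["ARIL20"] + 1e-12).all()
        np.testing.assert_allclose(table["FP"], -table["nCOM"], atol=1e-12)

    def test_fc_bounded_by_selection_ratio(self, rng):
        table = build_xai_table(self._cases(rng, 8))
        fc = table["FC"].dropna()
        # |A20|/|A5| is 4 up to rounding of the two selection counts
        assert (fc <= 4.5 + 1e-9).all()

    def test_mean_leakage_identity(self, rng):
        table = build_xai_table(self._cases(rng, 10))
        assert table["Leak20"].mean() == pytest.approx(
            1 - table["APIL20"].mean())

    def test_identical_pred_and_gt_masks_give_identical_tables(self, rng):
        gt_cases = self._cases(rng, 5, mode="gt")
        rng2 = np.random.default_rng(0)
        pred_cases = self._cases(rng2, 5, mode="pred")
        a = build_xai_table(gt_cases).drop(columns="mode")
        b = build_xai_table(pred_cases).drop(columns="mode")
        pd.testing.assert_frame_equal(a, b)
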