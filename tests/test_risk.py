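import numpy as np
import pandas as pd
import pytest

from pfasrisk.risk import (
    combine_risk,
    compute_exposures,
    legacy_share,
    rank_and_flag,
    reference_indices,
    risk_index,
)


@pytest.fixture(scope="module")
def exposures(occurrence):
    return compute_exposures(occurrence)


@pytest.fixture(scope="module")
def toxpi_scores_fixture(occurrence):
    # placeholder hazard scores; PFOA/PFOS carry their reported values
    s = pd.Series(0.5, index=occurrence.index)
    s["PFOA"], s["PFOS"] = 0.63, 0.70
    return s


class TestExposure:
    def test_extremes_of_the_registry_set(self, exposures):
        # PFHxA holds the set maximum (48.92 ng/L) at DF = 1
        assert exposures.loc["PFHxA", "magnitude"] == 1.0
        assert exposures.loc["PFHxA", "exposure"] == 1.0
        assert exposures.loc["PFHxA", "exposure_normalized"] == 1.0
        # the 0.00 ng/L compound anchors the minimum
        assert exposures.loc["HPFLCA_i n=6", "magnitude"] == 0.0
        assert exposures.loc["HPFLCA_i n=6", "exposure"] == 0.0

    def test_pfoa_worked_values(self, exposures):
        assert exposures.loc["PFOA", "magnitude"] == pytest.approx(0.76083, abs=1e-5)
        assert exposures.loc["PFOA", "exposure"] == pytest.approx(
            0.9796 * 37.22 / 48.92, abs=1e-9)

    def test_scale_invariance(self, occurrence):
        scaled = occurrence.copy()
        scaled["max_concentration"] *= 7.3
        a = compute_exposures(occurrence)["exposure_normalized"]
        b = compute_exposures(scaled)["exposure_normalized"]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_df_monotonicity(self, occurrence):
        """Raising one compound's DF never lowers its exposure."""
        bumped = occurrence.copy()
        base = compute_exposures(occurrence).loc["PFOS", "exposure"]
        bumped.loc["PFOS", "detection_frequency"] = 1.0
        assert compute_exposures(bumped).loc["PFOS", "exposure"] >= base

    def test_degenerate_set_rejected(self):
        occ = pd.DataFrame({"detection_frequency": [1.0, 1.0],
                            "max_concentration": [5.0, 5.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            compute_exposures(occ)

    def test_binned_mode_in_unit_interval(self, occurrence):
        out = compute_exposures(occurrence, binned=True)
        assert ((out["exposure_normalized"] >= 0)
                & (out["exposure_normalized"] <= 1)).all()


class TestRiskIndex:
    def test_product_and_bounds(self):
        assert risk_index(0.63, 0.74531) == pytest.approx(0.46955, abs=1e-4)
        assert risk_index(0.9, 0.0) == 0.0
        assert risk_index(1.0, 1.0) == 1.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            risk_index(1.2, 0.5)
        with pytest.raises(ValueError):
            risk_index(0.5, -0.1)


class TestReferences:
    def test_mcl_anchored_magnitude(self, toxpi_scores_fixture, occurrence):
        refs = reference_indices(toxpi_scores_fixture, occurrence)
        assert refs.loc["ref-PFOA", "magnitude"] == pytest.approx(
            4.0 / 48.92, abs=1e-5)
        assert refs.loc["ref-PFOS", "ri"] == pytest.approx(
            0.70 * 4.0 / 48.92, abs=1e-4)
        assert refs["reference"].all()

    def test_missing_base_rejected(self, occurrence):
        s = pd.Series(0.5, index=["PFOA"])
        with pytest.raises(ValueError, match="PFOS"):
            reference_indices(s, occurrence)

    def test_reference_at_cmax_has_unit_magnitude(self, toxpi_scores_fixture,
                                                  occurrence):
        refs = reference_indices(toxpi_scores_fixture, occurrence,
                                 ref_conc=48.92)
        assert refs.loc["ref-PFOA", "magnitude"] == pytest.approx(1.0)


class TestRanking:
    def test_high_concern_strictly_above_references(self, exposures,
                                                    toxpi_scores_fixture,
                                                    occurrence):
        rr = combine_risk(exposures, toxpi_scores_fixture)
        refs = reference_indices(toxpi_scores_fixture, occurrence)
        ranked = rank_and_flag(rr, refs)
        threshold = refs["ri"].max()
        flagged = ranked[ranked["high_concern"]]
        assert (flagged["ri"] > threshold).all()
        not_flagged = ranked[~ranked["high_concern"] & ~ranked["reference"]]
        assert (not_flagged["ri"] <= threshold).all()
        # zero-RI compounds are never high concern
        assert not ranked.loc[ranked["ri"] == 0.0, "high_concern"].any()

    def test_descending_order_and_permutation_invariance(self, exposures,
                                                         toxpi_scores_fixture,
                                                         occurrence):
        rr = combine_risk(exposures, toxpi_scores_fixture)
        refs = reference_indices(toxpi_scores_fixture, occurrence)
        a = rank_and_flag(rr, refs)
        assert (a["ri"].diff().dropna() <= 1e-15).all()
        shuffled = rr.sample(frac=1.0, random_state=3)
        b = rank_and_flag(shuffled, refs)
        assert list(a.index) == list(b.index)

    def test_constructed_three_exceeders(self, toxpi_scores_fixture):
        occ = pd.DataFrame(
            {"detection_frequency": [1.0, 1.0, 1.0, 0.9, 0.1, 0.05],
             "max_concentration": [100.0, 90.0, 80.0, 40.0, 5.0, 0.1]},
            index=["PFOA", "PFOS", "c3", "c4", "c5", "c6"])
        toxpi = pd.Series([0.63, 0.70, 0.9, 0.03, 0.2, 0.2], index=occ.index)
        exp = compute_exposures(occ)
        rr = combine_risk(exp, toxpi)
        refs = reference_indices(toxpi, occ)
        ranked = rank_and_flag(rr, refs)
        assert int(ranked["high_concern"].sum()) == 3


class TestLegacyShare:
    def test_registry_gives_83_percent(self, registry):
        assert legacy_share(registry) == 83

    def test_pure_sets(self, registry):
        legacy_only = [r for r in registry if r.legacy]
        novel_only = [r for r in registry if not r.legacy]
        assert legacy_share(legacy_only) == 100
        assert legacy_share(novel_only) == 0

    def test_zero_total_rejected(self, registry):
        from dataclasses import replace
        zeroed = [replace(r, max_concentration=0.0) for r in registry]
        with pytest.raises(ValueError):
            legacy_share(zeroed)
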