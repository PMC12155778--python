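import numpy as np
import pandas as pd
import pytest

from pfasrisk import chem, screening
from pfasrisk.chem import parse_formula
from pfasrisk.screening import (
    Evidence,
    ScreenConfig,
    assign_confidence,
    filter_rt,
    isotope_fit,
    match_suspects,
    run_screen,
    subtract_blank,
)
from pfasrisk.synthetic import (
    FeatureTable,
    Spectrum,
    gen_feature_table,
    gen_ms2_spectra,
    make_truth_set,
)


def _mini_table(rows):
    df = pd.DataFrame(rows, columns=["feature_id", "mz", "rt_min", "iso_m1",
                                     "iso_m2", "sample:S1", "blank:B1"])
    return FeatureTable(df, ("S1",), ("B1",))


class TestBlankSubtraction:
    @pytest.mark.parametrize("sample, blank, kept", [
        (600.0, 100.0, True),    # 600 > 5 x 100
        (500.0, 100.0, False),   # strict inequality
        (10.0, 0.0, True),       # zero blank always kept
    ])
    def test_five_fold_rule(self, sample, blank, kept):
        table = _mini_table([("F1", 400.0, 5.0, 0.1, 0.0, sample, blank)])
        out = subtract_blank(table, 5.0)
        assert (len(out.data) == 1) is kept

    def test_rejects_negative_factor(self):
        table = _mini_table([("F1", 400.0, 5.0, 0.1, 0.0, 1.0, 0.0)])
        with pytest.raises(ValueError):
            subtract_blank(table, -1.0)


class TestMassMatch:
    def test_exact_mass_matches_at_zero_ppm(self, registry):
        pfoa = next(r for r in registry if r.acronym == "PFOA")
        table = _mini_table([("F1", pfoa.theoretical_mz, 5.0, 0.09, 0.0, 1e5, 0.0)])
        cands = match_suspects(table, registry, tol_ppm=5.0)
        assert [c.compound.acronym for c in cands] == ["PFOA"]
        assert cands[0].ppm == pytest.approx(0.0, abs=1e-9)

    def test_six_ppm_offset_not_matched(self, registry):
        pfoa = next(r for r in registry if r.acronym == "PFOA")
        mz = pfoa.theoretical_mz * (1 + 6e-6)
        table = _mini_table([("F1", mz, 5.0, 0.09, 0.0, 1e5, 0.0)])
        assert match_suspects(table, registry, tol_ppm=5.0) == []

    def test_empty_suspect_list_warns(self, registry):
        table = _mini_table([("F1", 400.0, 5.0, 0.1, 0.0, 1e5, 0.0)])
        with pytest.warns(UserWarning):
            assert match_suspects(table, [], 5.0) == []


class TestIsotopeFit:
    def test_theoretical_envelope_scores_100(self):
        f = parse_formula("C8F15O2")
        env = chem.isotope_envelope(f)
        fit = isotope_fit(env, f)
        assert fit.score == pytest.approx(100.0)
        assert fit.passed

    def test_single_peak_envelope_fails_with_reason(self):
        fit = isotope_fit([1.0], parse_formula("C8F15O2"))
        assert not fit.passed and "isotopologue" in fit.reason

    def test_fifty_percent_m1_error_fails_on_intensity(self):
        f = parse_formula("C8F15O2")
        env = chem.isotope_envelope(f)
        fit = isotope_fit([env[0], env[1] * 1.5, env[2]], f)
        assert fit.max_intensity_dev == pytest.approx(50.0, abs=1e-6)
        assert not fit.passed


class TestRtFilter:
    def _cand(self, registry, rt):
        pfoa = next(r for r in registry if r.acronym == "PFOA")
        return screening.MatchCandidate("F1", pfoa, pfoa.theoretical_mz, rt, 0.0,
                                        passed_blank=True, passed_mass=True)

    def test_window_boundaries(self, registry):
        pred = {"PFOA": 10.0}
        assert len(filter_rt([self._cand(registry, 10.0)], pred)) == 1
        assert len(filter_rt([self._cand(registry, 11.6)], pred)) == 0

    def test_missing_prediction_policies(self, registry):
        kept = filter_rt([self._cand(registry, 10.0)], {}, missing_policy="keep")
        assert len(kept) == 1 and kept[0].rt_unfiltered
        assert filter_rt([self._cand(registry, 10.0)], {},
                         missing_policy="fail") == []


class TestConfidenceLevels:
    def test_standard_match_gives_level_1(self):
        ev = Evidence(standard_rt_match=True, standard_ms2_match=True,
                      isotope_pass=True, n_fragments_matched=3,
                      isomer_discriminating=True, rt_support=True)
        assert assign_confidence(ev) == "1"

    def test_two_fragments_discriminating(self):
        base = dict(isotope_pass=True, n_fragments_matched=2,
                    isomer_discriminating=True)
        assert assign_confidence(Evidence(**base, rt_support=True)) == "2a"
        assert assign_confidence(Evidence(**base, rt_support=False)) == "2b"

    def test_one_fragment_gives_3a_and_none_rejects(self):
        assert assign_confidence(Evidence(n_fragments_matched=1)) == "3a"
        assert assign_confidence(Evidence(n_fragments_matched=0)) == "rejected"


@pytest.fixture(scope="module")
def run(registry):
    truth = make_truth_set(registry, n_compounds=20, n_samples=5, seed=1)
    table = gen_feature_table(truth, 500, seed=1)
    spectra = gen_ms2_spectra(truth, table, seed=1)
    pred_rt = {c.record.acronym: c.rt_min for c in truth.compounds}
    hits, report = run_screen(table, spectra, registry, predicted_rt=pred_rt)
    return truth, table, hits, report


class TestFullCascade:

    def test_full_recovery_no_false_positives(self, run):
        truth, table, hits, report = run
        planted = set(table.truth_features.values())
        found = {h.candidate.feature_id for h in hits}
        assert found == planted

    def test_funnel_monotone(self, run):
        *_, report = run
        assert report.is_monotone()
        assert report.raw_peaks == 520

    def test_planted_sulfonate_hits_carry_so3(self, run):
        truth, table, hits, _ = run
        pfsa_hits = [h for h in hits if h.candidate.compound.class_id == "PFSA"]
        assert pfsa_hits
        so3 = parse_formula("SO3")
        for h in pfsa_hits:
            assert len(h.fragments) >= 3
            assert any(parse_formula(f.formula) == so3 for f in h.fragments)

    def test_standards_upgrade_to_level_1(self, registry):
        truth = make_truth_set(registry, n_compounds=10, n_samples=4, seed=6)
        table = gen_feature_table(truth, 100, seed=6)
        spectra = gen_ms2_spectra(truth, table, seed=6)
        pred_rt = {c.record.acronym: c.rt_min for c in truth.compounds}
        standards = {c.record.acronym for c in truth.compounds}
        hits, _ = run_screen(table, spectra, registry, predicted_rt=pred_rt,
                             standards=standards)
        assert hits and all(h.confidence_level == "1" for h in hits)

    def test_empty_table_empty_funnel(self, registry):
        table = _mini_table([])
        hits, report = run_screen(table, {}, registry)
        assert hits == [] and sum(report.as_dict().values()) == 0

    def test_tight_tolerance_loses_planted_hits(self, registry):
        """Shrinking the MS1 window below the mass jitter drops recovery."""
        truth = make_truth_set(registry, n_compounds=20, n_samples=5, seed=1)
        table = gen_feature_table(truth, 0, seed=1)
        spectra = gen_ms2_spectra(truth, table, seed=1)
        pred_rt = {c.record.acronym: c.rt_min for c in truth.compounds}
        hits, _ = run_screen(table, spectra, registry,
                             ScreenConfig(tol_ppm_ms1=0.1), predicted_rt=pred_rt)
        assert len(hits) < 20

    def test_survivors_monotone_in_tolerance(self, registry):
        """Relaxing the MS1 tolerance never decreases the survivor count."""
        truth = make_truth_set(registry, n_compounds=20, n_samples=5, seed=2,
                               sigma_ppm=2.0)
        table = gen_feature_table(truth, 100, seed=2)
        spectra = gen_ms2_spectra(truth, table, seed=2)
        pred_rt = {c.record.acronym: c.rt_min for c in truth.compounds}
        counts = []
        for tol in (0.5, 1.0, 2.0, 5.0, 10.0):
            hits, _ = run_screen(table, spectra, registry,
                                 ScreenConfig(tol_ppm_ms1=tol),
                                 predicted_rt=pred_rt)
            counts.append(len(hits))
        assert counts == sorted(counts)
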