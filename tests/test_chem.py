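import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfasrisk import chem
from pfasrisk.chem import (
    ELECTRON_MASS,
    ElementCounts,
    anion_mz,
    deprotonated,
    homologue_formula,
    isotope_envelope,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
    registry_summary,
)


@pytest.mark.parametrize(
    "text, expected",
    [
        ("CO2", {"C": 1, "O": 2}),
        ("C4HF9O3S", {"C": 4, "H": 1, "F": 9, "O": 3, "S": 1}),
        ("C2HF6NO4S2", {"C": 2, "H": 1, "F": 6, "N": 1, "O": 4, "S": 2}),
        ("Cl", {"Cl": 1}),
        ("C8HClF16O4S", {"C": 8, "H": 1, "Cl": 1, "F": 16, "O": 4, "S": 1}),
    ],
)
def test_parse_formula(text, expected):
    assert dict(parse_formula(text)) == expected


@pytest.mark.parametrize("bad", ["", "Xx3", "C4Qz", "c4"])
def test_parse_formula_rejects_unknown_symbols(bad):
    with pytest.raises(ValueError):
        parse_formula(bad)


@st.composite
def element_counts(draw):
    symbols = draw(st.lists(st.sampled_from(sorted(chem.ALLOWED_ELEMENTS)),
                            min_size=1, max_size=5, unique=True))
    return ElementCounts({s: draw(st.integers(1, 40)) for s in symbols})


@given(element_counts())
@settings(max_examples=200, deadline=None)
def test_parse_canonical_roundtrip(f):
    """parse_formula is the left inverse of canonical-text rendering."""
    assert parse_formula(f.canonical()) == f


@pytest.mark.parametrize(
    "formula, mass",
    [
        ("CO2", 43.98983),   # carboxylate neutral loss
        ("HF", 20.00623),
        ("C", 12.00000),
    ],
)
def test_monoisotopic_mass(formula, mass):
    assert monoisotopic_mass(parse_formula(formula)) == pytest.approx(mass, abs=5e-6)


@pytest.mark.parametrize(
    "formula, mz",
    [
        ("SO3", 79.95736),   # sulfonate diagnostic ion
        ("SO2F", 82.96085),
        ("SO3F", 98.95577),
    ],
)
def test_anion_mz_diagnostic_ions(formula, mz):
    assert round(anion_mz(parse_formula(formula), 1), 5) == mz


def test_anion_mz_rejects_zero_charge():
    with pytest.raises(ValueError):
        anion_mz(parse_formula("SO3"), 0)


@given(element_counts())
@settings(max_examples=100, deadline=None)
def test_electron_mass_consistency(f):
    """anion_mz(f, 1) - monoisotopic_mass(f) equals one electron mass."""
    assert anion_mz(f, 1) - monoisotopic_mass(f) == pytest.approx(
        ELECTRON_MASS, abs=1e-7)


@pytest.mark.parametrize(
    "observed, theoretical, expected",
    [
        (79.95736, 79.95736, 0.0),
        (79.95776, 79.95736, 5.00),
        (412.96440, 412.96647, -5.01),
    ],
)
def test_ppm_error(observed, theoretical, expected):
    assert ppm_error(observed, theoretical) == pytest.approx(expected, abs=5e-3)


def test_ppm_error_rejects_nonpositive_reference():
    with pytest.raises(ValueError):
        ppm_error(100.0, 0.0)


@pytest.mark.parametrize(
    "class_id, n, expected",
    [
        ("PFCA", 4, "C4HF7O2"),
        ("PFCA", 3, "C3HF5O2"),
        ("PFSA", 4, "C4HF9O3S"),
        ("PFECA", 6, "C6HF11O3"),
        ("FTSA", 8, "C8H5F13O3S"),
    ],
)
def test_homologue_formula(class_id, n, expected):
    assert homologue_formula(class_id, n) == parse_formula(expected)


def test_homologue_formula_rejects_out_of_range():
    with pytest.raises(ValueError):
        homologue_formula("PFCA", 2)
    with pytest.raises(ValueError):
        homologue_formula("no-such-class", 4)


def test_homologue_masses_increase_by_cf2():
    """Within each class, homologue masses climb by one CF2 (49.99681 Da)."""
    cf2 = monoisotopic_mass(parse_formula("CF2"))
    assert cf2 == pytest.approx(49.99681, abs=1e-4)
    for class_id, lo, hi in [("PFCA", 3, 12), ("PFSA", 3, 8), ("H-PFCA", 4, 6)]:
        masses = [monoisotopic_mass(homologue_formula(class_id, n))
                  for n in range(lo, hi + 1)]
        for a, b in zip(masses, masses[1:]):
            assert b - a == pytest.approx(cf2, abs=1e-4)


def test_registry_matches_homologue_rules(registry):
    """Every packaged formula is reproduced by its class's homologue rule."""
    for rec in registry:
        assert homologue_formula(rec.class_id, rec.n_carbons) == rec.formula


def test_registry_summary_counts(registry):
    s = registry_summary(registry)
    assert s["n_compounds"] == 30
    assert len(s["by_class"]) == 11
    assert (s["legacy"], s["novel"]) == (16, 14)
    # CL column of the packaged table: 19 standard-confirmed identifications
    assert s["by_confidence_level"]["1"] == 19
    assert sum(s["by_class"].values()) == s["n_compounds"]


def test_registry_summary_empty_list_warns():
    with pytest.warns(UserWarning):
        s = registry_summary([])
    assert s["n_compounds"] == 0 and s["by_class"] == {}


def test_registry_rejects_bad_rows(tmp_path, registry):
    path = tmp_path / "bad.tsv"
    header = ("acronym\tclass_id\tn_carbons\tformula\tconfidence_level\t"
              "detection_frequency_pct\tmax_conc_ng_L\tlegacy\n")
    path.write_text(header + "X\tPFCA\t4\tC4HF7O2\t1\t150.0\t1.0\ttrue\n")
    with pytest.raises(ValueError, match="row 2"):
        chem.load_registry(path)
    path.write_text(header.replace("formula\t", ""))
    with pytest.raises(ValueError, match="missing"):
        chem.load_registry(path)


def test_fragment_rules_cover_all_classes(fragment_rules, registry):
    classes = {r.class_id for r in registry}
    assert classes <= set(fragment_rules)
    for class_id, rules in fragment_rules.items():
        assert any(r.required for r in rules)


def test_fragment_template_resolution(fragment_rules):
    pfsa_chain = next(r for r in fragment_rules["PFSA"]
                      if "n" in r.formula_template)
    assert pfsa_chain.resolve(8) == parse_formula("C8F17")
    pfca_loss = next(r for r in fragment_rules["PFCA"] if r.kind == "neutral-loss")
    assert monoisotopic_mass(pfca_loss.resolve(8)) == pytest.approx(43.98983, abs=1e-5)


def test_isotope_envelope_m1_matches_per_atom_oracle():
    """M+1 abundance agrees with the independent one-heavy-atom expansion."""
    f = parse_formula("C8F15O2")  # PFOA anion
    env = isotope_envelope(f)
    # oracle: probability of exactly one +1 substitution, relative to M
    pattern = chem._ISOTOPE_PATTERN
    m1_oracle = sum(
        count * pattern[el][1] / pattern[el][0]
        for el, count in f.items() if len(pattern[el]) > 1
    )
    assert env[1] == pytest.approx(m1_oracle, rel=1e-6)
    # dominated by carbon-13: about 8 x 1.07 %
    assert env[1] == pytest.approx(8 * 0.0107, rel=0.05)


def test_isotope_envelope_chlorine_m2():
    """A one-chlorine formula shows the characteristic ~24/76 M+2."""
    env = isotope_envelope(parse_formula("C8ClF16O4S"))
    assert env[2] > 0.3  # Cl-37 plus S-34


def test_deprotonated_anion_mass():
    pfoa = parse_formula("C8HF15O2")
    assert deprotonated(pfoa) == parse_formula("C8F15O2")
    assert anion_mz(deprotonated(pfoa)) == pytest.approx(412.9664, abs=5e-4)
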