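"""Seeded generators for every input the pipeline consumes.

Real acquisitions for this kind of study (SPE-extracted drinking water run on
an LC-Orbitrap in negative mode) are not redistributable, so each stage is
exercised on synthetic data with planted ground truth: homologue features at
exact anion masses with ppm jitter, class-diagnostic MS2 fragments, linear
descriptor→response-factor/retention-time relationships, hazard-attribute
tables with a planted chain-length trend, and group-structured contamination
profiles.  All generators are pure functions of (parameters, seed).

Intensity noise is lognormal (multiplicative), matching typical ESI response
behaviour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (
    CompoundRecord,
    FragmentRule,
    anion_mz,
    isotope_envelope,
    load_fragment_rules,
    load_registry,
    monoisotopic_mass,
)

__all__ = [
    "TruthCompound",
    "TruthSet",
    "FeatureTable",
    "Spectrum",
    "GroupSpec",
    "DescriptorTruth",
    "make_truth_set",
    "gen_feature_table",
    "gen_ms2_spectra",
    "gen_descriptor_matrix",
    "gen_attribute_table",
    "gen_profile_matrix",
    "write_feature_table_csv",
    "read_feature_table_csv",
    "write_spectra_mgf",
    "read_spectra_mgf",
    "write_truth_json",
]


@dataclass(frozen=True)
class TruthCompound:
    """Planted ground truth for one compound."""

    record: CompoundRecord
    concentrations: np.ndarray  # ng/L per sample
    rf: float                   # response counts per ng/L
    rt_min: float

    def __post_init__(self):
        if np.any(np.asarray(self.concentrations) < 0):
            raise ValueError(f"{self.record.acronym}: negative concentration")
        if self.rf <= 0:
            raise ValueError(f"{self.record.acronym}: RF must be > 0")


@dataclass(frozen=True)
class TruthSet:
    """Planted compounds plus the noise model of the simulated acquisition."""

    compounds: tuple[TruthCompound, ...]
    sample_ids: tuple[str, ...]
    blank_ids: tuple[str, ...] = ("B1",)
    sigma_ppm: float = 1.0          # m/z jitter SD
    rt_sd_min: float = 0.2          # RT jitter SD
    intensity_cv: float = 0.2       # lognormal CV of responses
    envelope_cv: float = 0.02       # isotopologue relative-intensity noise
    blank_fraction: float = 0.05    # blank contamination as fraction of mean signal

    def __post_init__(self):
        for p in (self.sigma_ppm, self.rt_sd_min, self.intensity_cv,
                  self.envelope_cv, self.blank_fraction):
            if not np.isfinite(p) or p < 0:
                raise ValueError("noise parameters must be finite and >= 0")


@dataclass
class FeatureTable:
    """Picked-peak table: one row per LC-HRMS feature.

    ``data`` columns: feature_id, mz, rt_min, iso_m1, iso_m2, then one
    ``sample:<id>`` column per sample and ``blank:<id>`` per blank.  Isotope
    envelopes are relative to M = 1.  ``truth_features`` maps planted
    acronyms to their feature ids (ground-truth sidecar, not an input to the
    screening cascade).
    """

    data: pd.DataFrame
    sample_ids: tuple[str, ...]
    blank_ids: tuple[str, ...]
    truth_features: dict[str, str] = field(default_factory=dict)

    @property
    def sample_columns(self) -> list[str]:
        return [f"sample:{s}" for s in self.sample_ids]

    @property
    def blank_columns(self) -> list[str]:
        return [f"blank:{b}" for b in self.blank_ids]


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS2 spectrum attached to a precursor feature."""

    feature_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray


def make_truth_set(
    registry: list[CompoundRecord] | None = None,
    n_compounds: int = 20,
    n_samples: int = 5,
    seed: int = 0,
    **noise_overrides,
) -> TruthSet:
    """Convenience TruthSet built from registry compounds.

    Concentrations are lognormal around each compound's registry maximum
    (floored at 0.5 ng/L so every planted compound is detectable), RFs are
    lognormal around 1e4 counts per ng/L, and RTs increase with chain length
    across a 2-18 min gradient window, as reversed-phase elution of a
    homologue series does.
    """
    if registry is None:
        registry = load_registry()
    if not 1 <= n_compounds <= len(registry):
        raise ValueError(f"n_compounds must be in [1, {len(registry)}]")
    rng = np.random.default_rng(seed)
    chosen = list(registry)[:n_compounds]
    n_max = max(r.n_carbons for r in registry)
    compounds = []
    for rec in chosen:
        base = max(rec.max_concentration, 0.5)
        conc = base * rng.lognormal(mean=-0.5, sigma=0.5, size=n_samples)
        rf = 1e4 * rng.lognormal(mean=0.0, sigma=0.3)
        rt = 2.0 + 16.0 * rec.n_carbons / (n_max + 1) + rng.normal(0, 0.3)
        compounds.append(TruthCompound(rec, conc, rf, float(np.clip(rt, 1.0, 19.0))))
    return TruthSet(
        compounds=tuple(compounds),
        sample_ids=tuple(f"S{i + 1}" for i in range(n_samples)),
        **noise_overrides,
    )


def gen_feature_table(
    truth: TruthSet,
    n_noise_peaks: int,
    seed: int,
    mz_range: tuple[float, float] = (100.0, 1000.0),
    rt_range: tuple[float, float] = (1.0, 20.0),
    exclusion_ppm: float = 5.0,
) -> FeatureTable:
    """Simulate a picked-peak feature table with planted truth and noise peaks.

    Each planted compound yields one feature at its theoretical anion m/z
    perturbed by Normal(0, sigma_ppm) relative error, with per-sample
    intensity RF x concentration x lognormal noise and blanks carrying the
    stated contamination fraction.  Noise peaks are uniform over m/z and RT
    and are redrawn until they sit more than ``exclusion_ppm`` away from
    every suspect anion mass, so they can never be mass-matched by accident.
    """
    if n_noise_peaks < 0:
        raise ValueError("n_noise_peaks must be >= 0")
    rng = np.random.default_rng(seed)
    suspect_mz = np.array([c.record.theoretical_mz for c in truth.compounds])

    rows = []
    truth_features: dict[str, str] = {}
    fid = 0
    for c in truth.compounds:
        fid += 1
        feature_id = f"F{fid:05d}"
        truth_features[c.record.acronym] = feature_id
        theo = c.record.theoretical_mz
        mz = theo * (1.0 + rng.normal(0.0, truth.sigma_ppm) * 1e-6)
        rt = c.rt_min + rng.normal(0.0, truth.rt_sd_min)
        responses = c.rf * np.asarray(c.concentrations) * rng.lognormal(
            mean=0.0, sigma=truth.intensity_cv, size=len(truth.sample_ids))
        blank_level = truth.blank_fraction * float(np.mean(responses))
        blanks = blank_level * rng.lognormal(0.0, truth.intensity_cv,
                                             size=len(truth.blank_ids))
        env = isotope_envelope(c.record.anion_formula)
        m1 = env[1] * rng.lognormal(0.0, truth.envelope_cv)
        m2 = env[2] * rng.lognormal(0.0, truth.envelope_cv) if env[2] > 0 else 0.0
        rows.append((feature_id, mz, rt, m1, m2, *responses, *blanks))

    for _ in range(n_noise_peaks):
        fid += 1
        while True:
            mz = rng.uniform(*mz_range)
            if suspect_mz.size == 0:
                break
            ppm = 1e6 * np.abs(mz - suspect_mz) / suspect_mz
            if np.all(ppm > exclusion_ppm):
                break
        rt = rng.uniform(*rt_range)
        level = rng.lognormal(mean=10.0, sigma=1.5)
        responses = level * rng.lognormal(0.0, 0.5, size=len(truth.sample_ids))
        blanks = level * rng.uniform(0.0, 0.5, size=len(truth.blank_ids))
        m1 = rng.uniform(0.0, 0.5)
        m2 = rng.uniform(0.0, 0.2)
        rows.append((f"F{fid:05d}", mz, rt, m1, m2, *responses, *blanks))

    columns = (["feature_id", "mz", "rt_min", "iso_m1", "iso_m2"]
               + [f"sample:{s}" for s in truth.sample_ids]
               + [f"blank:{b}" for b in truth.blank_ids])
    data = pd.DataFrame(rows, columns=columns)
    return FeatureTable(data=data, sample_ids=truth.sample_ids,
                        blank_ids=truth.blank_ids, truth_features=truth_features)


def gen_ms2_spectra(
    truth: TruthSet,
    table: FeatureTable,
    seed: int,
    rules: dict[str, list[FragmentRule]] | None = None,
    sigma_ppm: float = 2.0,
    n_distractors: int = 10,
) -> dict[str, Spectrum]:
    """MS2 spectra keyed by feature id.

    Planted compounds get all their class's diagnostic fragments (anion
    fragments at the fragment anion m/z, neutral losses as precursor minus
    loss mass) with Normal(0, sigma_ppm) jitter plus random distractor
    peaks; noise features get distractor-only spectra.
    """
    if rules is None:
        rules = load_fragment_rules()
    rng = np.random.default_rng(seed)
    by_acronym = {c.record.acronym: c for c in truth.compounds}
    feature_of = table.truth_features
    spectra: dict[str, Spectrum] = {}

    mz_by_fid = dict(zip(table.data["feature_id"], table.data["mz"]))
    planted_fids = set(feature_of.values())

    for acr, fid in feature_of.items():
        c = by_acronym[acr]
        if c.record.class_id not in rules:
            raise ValueError(f"no fragment rules for class {c.record.class_id}")
        precursor = mz_by_fid[fid]
        peaks = []
        for rule in rules[c.record.class_id]:
            frag = rule.resolve(c.record.n_carbons)
            if rule.kind == "anion-fragment":
                target = anion_mz(frag)
            else:  # neutral loss observed as the complementary product ion
                target = precursor - monoisotopic_mass(frag)
            if target <= 0:
                continue
            peaks.append(target * (1.0 + rng.normal(0.0, sigma_ppm) * 1e-6))
        n_frag = len(peaks)
        distract = rng.uniform(50.0, precursor, size=n_distractors)
        mz = np.concatenate([peaks, distract])
        inten = np.concatenate([rng.lognormal(8, 0.5, n_frag),
                                rng.lognormal(5, 1.0, n_distractors)])
        order = np.argsort(mz)
        spectra[fid] = Spectrum(fid, precursor, mz[order], inten[order])

    for fid, precursor in mz_by_fid.items():
        if fid in planted_fids:
            continue
        mz = np.sort(rng.uniform(50.0, max(precursor, 60.0), size=n_distractors))
        inten = rng.lognormal(5, 1.0, n_distractors)
        spectra[fid] = Spectrum(fid, precursor, mz, inten)
    return spectra


@dataclass(frozen=True)
class DescriptorTruth:
    """Synthetic descriptor matrix with planted linear responses."""

    X: pd.DataFrame                # compounds x descriptors, standardized
    rf: np.ndarray                 # response factors (offset + linear + noise)
    rt: np.ndarray                 # retention times, min
    informative: tuple[str, ...]   # descriptor columns carrying signal
    beta_rf: np.ndarray            # coefficients on the informative columns
    beta_rt: np.ndarray


def gen_descriptor_matrix(
    n_compounds: int,
    n_descriptors: int = 200,
    k_informative: int = 5,
    noise_sd: float = 0.1,
    seed: int = 0,
    rf_offset: float = 5.0,
    rt_offset: float = 10.0,
) -> DescriptorTruth:
    """Descriptor matrix with RF and RT linear in ``k_informative`` columns.

    Descriptors are iid standard normal; the informative coefficient vectors
    are scaled to unit norm so the linear signal has unit variance, making
    ``noise_sd`` directly interpretable as a fraction of the response SD.
    The descriptor count defaults to 200 rather than the thousands a full
    2-D descriptor suite produces, which keeps desk-scale model selection
    fast; pass a larger value for fidelity runs.
    """
    if n_compounds < 10:
        raise ValueError("need at least 10 compounds for an 8:2 split")
    if k_informative > n_descriptors:
        raise ValueError("k_informative cannot exceed n_descriptors")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_compounds, n_descriptors))
    cols = tuple(f"D{j + 1:04d}" for j in range(n_descriptors))
    idx = rng.choice(n_descriptors, size=k_informative, replace=False)
    informative = tuple(cols[j] for j in idx)

    def draw_beta():
        b = rng.normal(size=k_informative)
        return b / np.linalg.norm(b)

    beta_rf, beta_rt = draw_beta(), draw_beta()
    signal = X[:, idx]
    rf = rf_offset + signal @ beta_rf + rng.normal(0.0, noise_sd, n_compounds)
    rt = rt_offset + signal @ beta_rt + rng.normal(0.0, noise_sd, n_compounds)
    Xdf = pd.DataFrame(X, columns=list(cols))
    return DescriptorTruth(Xdf, rf, rt, informative, beta_rf, beta_rt)


# Attribute models: (base, slope per carbon, noise SD, log10 scale?).  Signs
# are chosen so that, after the Table-2 scaling transform, hazard increases
# with chain length — longer chains degrade slower and bioaccumulate more.
_ATTRIBUTE_MODELS: dict[str, tuple[float, float, float, bool]] = {
    "Biowin1": (3.5, -0.20, 0.15, False),
    "Biowin3": (2.8, -0.15, 0.15, False),
    "Biowin5": (2.2, -0.12, 0.15, False),
    "BAF": (-0.5, 0.30, 0.10, True),
    "LogKow": (-1.0, 0.60, 0.20, False),
    "Fish LC50": (2.5, -0.25, 0.15, True),
    "Daphnid LC50": (2.3, -0.22, 0.15, True),
    "Green Algae EC50": (2.1, -0.20, 0.15, True),
    "Carcinogenicity": (0.2, 0.02, 0.08, False),
    "Developmental toxicity": (0.2, 0.02, 0.08, False),
    "Mutagenicity": (0.15, 0.01, 0.08, False),
    "Skin sensitization": (0.2, 0.015, 0.08, False),
    "Oral rat LD50": (3.5, -0.15, 0.10, True),
    "ERa": (50.0, 2.0, 4.0, False),
    "ERb": (48.0, 2.0, 4.0, False),
    "AR": (45.0, 1.8, 4.0, False),
    "PPARa": (55.0, 2.2, 4.0, False),
    "TRa": (42.0, 1.5, 4.0, False),
    "TRb": (40.0, 1.5, 4.0, False),
}


def gen_attribute_table(
    registry: list[CompoundRecord] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Compound x hazard-attribute raw values with a chain-length trend.

    Emulates externally produced QSAR/docking outputs (biodegradation
    probabilities, BAF, logKow, aquatic LC50/EC50s, in-silico toxicity calls,
    receptor docking scores) for each registry compound.  Values are drawn
    from plausible ranges with persistence/bioaccumulation increasing in
    carbon number, mirroring the tendency of longer-chain PFAS to score as
    more hazardous.  The real pipeline consumes such values, never computes
    them.
    """
    if registry is None:
        registry = load_registry()
    rng = np.random.default_rng(seed)
    rows = {}
    for rec in registry:
        n = rec.n_carbons
        vals = {}
        for attr, (base, slope, sd, log_scale) in _ATTRIBUTE_MODELS.items():
            v = base + slope * n + rng.normal(0.0, sd)
            vals[attr] = 10.0 ** v if log_scale else v
        rows[rec.acronym] = vals
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "compound"
    return df[list(_ATTRIBUTE_MODELS)]


@dataclass(frozen=True)
class GroupSpec:
    """Mean contamination profile of one sample group (log10 ng/L)."""

    name: str
    n_samples: int
    mean_log10: np.ndarray
    sd_log10: float = 0.1

    def __post_init__(self):
        if self.n_samples < 3:
            raise ValueError(f"group {self.name}: need >= 3 samples")
        if self.sd_log10 < 0:
            raise ValueError(f"group {self.name}: negative spread")


def gen_profile_matrix(
    group_specs: list[GroupSpec],
    seed: int = 0,
    compound_names: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Samples x compounds concentration matrix with group labels.

    Each group's samples scatter lognormally around the group's mean
    composition vector.  Returns (matrix, labels).
    """
    if len(group_specs) < 2:
        raise ValueError("need at least two groups")
    p = len(group_specs[0].mean_log10)
    if any(len(g.mean_log10) != p for g in group_specs):
        raise ValueError("all groups must cover the same compounds")
    rng = np.random.default_rng(seed)
    if compound_names is None:
        compound_names = [f"C{j + 1:03d}" for j in range(p)]
    blocks, labels, index = [], [], []
    for g in group_specs:
        log10 = g.mean_log10 + rng.normal(0.0, g.sd_log10, size=(g.n_samples, p))
        blocks.append(10.0 ** log10)
        labels.extend([g.name] * g.n_samples)
        index.extend(f"{g.name}-{i + 1}" for i in range(g.n_samples))
    X = pd.DataFrame(np.vstack(blocks), index=index, columns=compound_names)
    return X, pd.Series(labels, index=index, name="group")


# --------------------------------------------------------------------------
# Writers / readers (CSV for feature tables, MGF for spectra, JSON for truth)

def write_feature_table_csv(table: FeatureTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_feature_table_csv(path) -> FeatureTable:
    df = pd.read_csv(path)
    samples = tuple(c.split(":", 1)[1] for c in df.columns if c.startswith("sample:"))
    blanks = tuple(c.split(":", 1)[1] for c in df.columns if c.startswith("blank:"))
    return FeatureTable(data=df, sample_ids=samples, blank_ids=blanks)


def write_spectra_mgf(spectra: dict[str, Spectrum], path) -> None:
    """Write spectra to MGF; TITLE carries the feature id."""
    from pyteomics import mgf

    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {"title": s.feature_id, "pepmass": s.precursor_mz, "charge": "1-"},
        }
        for s in spectra.values()
    ]
    mgf.write(entries, output=str(path), file_mode="w")


def read_spectra_mgf(path) -> dict[str, Spectrum]:
    from pyteomics import mgf

    spectra = {}
    with mgf.MGF(str(path)) as reader:
        for entry in reader:
            fid = entry["params"]["title"]
            pep = entry["params"]["pepmass"]
            precursor = float(pep[0] if isinstance(pep, (tuple, list)) else pep)
            spectra[fid] = Spectrum(fid, precursor,
                                    np.asarray(entry["m/z array"], dtype=float),
                                    np.asarray(entry["intensity array"], dtype=float))
    return spectra


def write_truth_json(truth: TruthSet, path) -> None:
    payload = {
        "sample_ids": list(truth.sample_ids),
        "blank_ids": list(truth.blank_ids),
        "noise": {
            "sigma_ppm": truth.sigma_ppm,
            "rt_sd_min": truth.rt_sd_min,
            "intensity_cv": truth.intensity_cv,
            "envelope_cv": truth.envelope_cv,
            "blank_fraction": truth.blank_fraction,
        },
        "compounds": [
            {
                "acronym": c.record.acronym,
                "class_id": c.record.class_id,
                "concentrations_ng_L": list(map(float, c.concentrations)),
                "rf": c.rf,
                "rt_min": c.rt_min,
            }
            for c in truth.compounds
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
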