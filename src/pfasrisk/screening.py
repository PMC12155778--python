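"""Suspect-screening cascade for PFAS in LC-HRMS feature tables.

Filters are applied in acquisition-practice order — blank subtraction,
exact-mass match, isotope-pattern fit, retention-time window, diagnostic
fragment annotation — and each surviving candidate is assigned a tiered
identification confidence level (1, 2a, 2b, 3a).  A funnel report records
how many features survive each stage.

Thresholds default to the strict literal reading of the screening criteria:
sample intensity > 5x blank, |ppm| < 5 at MS1, isotope fit > 70% with every
isotopologue within 30% intensity and 5 ppm mass deviation, |RT error| <
1.5 min, fragments within 10 ppm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import (
    CompoundRecord,
    FragmentRule,
    anion_mz,
    isotope_envelope,
    monoisotopic_mass,
    ppm_error,
)
from .synthetic import FeatureTable, Spectrum

__all__ = [
    "ScreenConfig",
    "MatchCandidate",
    "MatchedFragment",
    "AnnotatedHit",
    "IsotopeFit",
    "ScreenReport",
    "subtract_blank",
    "match_suspects",
    "isotope_fit",
    "filter_rt",
    "annotate_fragments",
    "assign_confidence",
    "run_screen",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Tolerances of the screening cascade (strict inequalities throughout)."""

    blank_factor: float = 5.0
    tol_ppm_ms1: float = 5.0
    tol_ppm_ms2: float = 10.0
    rt_tol_min: float = 1.5
    isotope_fit_threshold: float = 70.0   # percent
    isotope_intensity_dev: float = 30.0   # percent, per isotopologue
    isotope_mass_dev_ppm: float = 5.0
    isotope_min_rel_abundance: float = 0.01  # isotopologues below this are not scored
    rt_missing_policy: str = "keep"       # "keep" (flag unfiltered) or "fail"
    dedup_rt_window_min: float = 0.2


@dataclass(frozen=True)
class MatchCandidate:
    """A feature <-> suspect pair with per-stage filter flags.

    Flags are True/False once a stage has been evaluated and None while a
    candidate has not reached it (later filters run only on survivors).
    """

    feature_id: str
    compound: CompoundRecord
    observed_mz: float
    rt_min: float
    ppm: float
    passed_blank: bool | None = None
    passed_mass: bool | None = None
    passed_isotope: bool | None = None
    passed_rt: bool | None = None
    rt_unfiltered: bool = False  # no RT prediction was available
    passed_fragment: bool | None = None


@dataclass(frozen=True)
class MatchedFragment:
    rule: FragmentRule
    formula: str
    theoretical_mz: float
    observed_mz: float
    ppm: float


@dataclass(frozen=True)
class AnnotatedHit:
    candidate: MatchCandidate
    fragments: tuple[MatchedFragment, ...]
    confidence_level: str  # "1" | "2a" | "2b" | "3a" | "rejected"


@dataclass(frozen=True)
class IsotopeFit:
    score: float                 # percent
    max_intensity_dev: float     # percent
    max_mass_dev_ppm: float
    passed: bool
    reason: str = ""


@dataclass
class ScreenReport:
    """Funnel counts, in features, non-increasing along the cascade."""

    raw_peaks: int = 0
    post_blank: int = 0
    mass_matched: int = 0
    post_dedup: int = 0
    annotated: int = 0
    identified: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "raw_peaks": self.raw_peaks,
            "post_blank": self.post_blank,
            "mass_matched": self.mass_matched,
            "post_dedup": self.post_dedup,
            "annotated": self.annotated,
            "identified": self.identified,
        }

    def is_monotone(self) -> bool:
        seq = list(self.as_dict().values())
        return all(a >= b for a, b in zip(seq, seq[1:]))


def subtract_blank(table: FeatureTable, blank_factor: float = 5.0) -> FeatureTable:
    """Keep features whose max sample intensity exceeds ``blank_factor`` x max blank.

    The inequality is strict; features with zero blank signal (or no blank
    columns at all) are always kept.
    """
    if blank_factor < 0:
        raise ValueError("blank_factor must be >= 0")
    df = table.data
    sample_max = df[table.sample_columns].max(axis=1)
    if table.blank_columns:
        blank_max = df[table.blank_columns].max(axis=1)
    else:
        blank_max = pd.Series(0.0, index=df.index)
    keep = sample_max > blank_factor * blank_max
    return FeatureTable(
        data=df.loc[keep].reset_index(drop=True),
        sample_ids=table.sample_ids,
        blank_ids=table.blank_ids,
        truth_features=table.truth_features,
    )


def match_suspects(
    table: FeatureTable,
    suspects: list[CompoundRecord],
    tol_ppm: float = 5.0,
) -> list[MatchCandidate]:
    """Exact-mass match of every feature against every suspect anion m/z.

    One candidate per (feature, suspect) pair with |ppm| < ``tol_ppm``;
    a feature may match several suspects.
    """
    if not suspects:
        warnings.warn("empty suspect list: no candidates generated")
        return []
    theo = np.array([s.theoretical_mz for s in suspects])
    out: list[MatchCandidate] = []
    for row in table.data.itertuples(index=False):
        ppm = 1e6 * (row.mz - theo) / theo
        for j in np.flatnonzero(np.abs(ppm) < tol_ppm):
            out.append(MatchCandidate(
                feature_id=row.feature_id,
                compound=suspects[j],
                observed_mz=row.mz,
                rt_min=row.rt_min,
                ppm=float(ppm[j]),
                passed_blank=True,
                passed_mass=True,
            ))
    return out


def isotope_fit(
    envelope: tuple[float, ...] | list[float],
    formula,
    config: ScreenConfig = ScreenConfig(),
    envelope_mz_dev_ppm: tuple[float, ...] | None = None,
) -> IsotopeFit:
    """Score an observed isotope envelope against the formula's theoretical one.

    ``envelope`` holds relative intensities at M, M+1, M+2 with M normalized
    to 1.  Score = 100 x (1 - sum|obs - theo| / sum theo).  Passing requires
    score above the fit threshold AND every scored isotopologue within the
    intensity-deviation bound (isotopologues below ``isotope_min_rel_abundance``
    carry too little signal to score) AND every mass deviation inside the ppm
    bound.  Feature tables usually report envelope intensities only; pass
    ``envelope_mz_dev_ppm`` when per-isotopologue mass errors are known.
    """
    obs = [v for v in envelope if v is not None and np.isfinite(v)]
    if len(obs) < 2:
        return IsotopeFit(0.0, float("inf"), float("inf"), False,
                          reason="envelope has fewer than 2 isotopologues")
    theo = isotope_envelope(formula, n_peaks=len(obs))
    abs_dev = [abs(o - t) for o, t in zip(obs, theo)]
    score = 100.0 * (1.0 - sum(abs_dev) / sum(theo))
    rel_devs = [100.0 * d / t for d, t, in zip(abs_dev, theo)
                if t >= config.isotope_min_rel_abundance]
    max_int_dev = max(rel_devs) if rel_devs else 0.0
    if envelope_mz_dev_ppm is None:
        max_mass_dev = 0.0
    else:
        max_mass_dev = max(abs(d) for d in envelope_mz_dev_ppm)
    passed = (score > config.isotope_fit_threshold
              and max_int_dev < config.isotope_intensity_dev
              and max_mass_dev < config.isotope_mass_dev_ppm)
    return IsotopeFit(score, max_int_dev, max_mass_dev, passed)


def filter_rt(
    candidates: list[MatchCandidate],
    predicted_rt: dict[str, float] | None,
    tol_min: float = 1.5,
    missing_policy: str = "keep",
) -> list[MatchCandidate]:
    """Keep candidates with |observed RT - predicted RT| < ``tol_min``.

    Candidates whose suspect has no RT prediction are retained flagged
    unfiltered under the default policy, or dropped with ``missing_policy=
    "fail"``.
    """
    predicted_rt = predicted_rt or {}
    out = []
    for c in candidates:
        pred = predicted_rt.get(c.compound.acronym)
        if pred is None:
            if missing_policy == "keep":
                out.append(replace(c, passed_rt=True, rt_unfiltered=True))
            continue
        if abs(c.rt_min - pred) < tol_min:
            out.append(replace(c, passed_rt=True))
    return out


def annotate_fragments(
    candidate: MatchCandidate,
    spectrum: Spectrum | None,
    rules: dict[str, list[FragmentRule]],
    tol_ppm: float = 10.0,
) -> list[MatchedFragment]:
    """Match class-diagnostic fragments against a candidate's MS2 spectrum.

    Anion fragments are compared against spectrum peaks directly; neutral
    losses against (precursor - peak) mass differences.  An empty or missing
    spectrum yields zero matches.
    """
    class_rules = rules.get(candidate.compound.class_id)
    if not class_rules:
        raise ValueError(f"no fragment rules for class {candidate.compound.class_id}")
    if spectrum is None or len(spectrum.mz) == 0:
        return []
    matches: list[MatchedFragment] = []
    for rule in class_rules:
        frag = rule.resolve(candidate.compound.n_carbons)
        if rule.kind == "anion-fragment":
            target = anion_mz(frag)
        else:
            target = candidate.observed_mz - monoisotopic_mass(frag)
        if target <= 0:
            continue
        ppm = 1e6 * (spectrum.mz - target) / target
        hits = np.flatnonzero(np.abs(ppm) < tol_ppm)
        if hits.size:
            best = hits[np.argmin(np.abs(ppm[hits]))]
            matches.append(MatchedFragment(
                rule=rule,
                formula=frag.canonical(),
                theoretical_mz=target,
                observed_mz=float(spectrum.mz[best]),
                ppm=float(ppm[best]),
            ))
    return matches


@dataclass(frozen=True)
class Evidence:
    """Identification evidence feeding the confidence-level rules."""

    standard_rt_match: bool = False
    standard_ms2_match: bool = False
    isotope_pass: bool = False
    n_fragments_matched: int = 0
    isomer_discriminating: bool = False
    rt_support: bool = False  # literature/predicted RT agrees (splits 2a vs 2b)


def assign_confidence(evidence: Evidence) -> str:
    """Tiered identification confidence.

    Level 1 requires a full authentic-standard match (RT + MS2 + isotope
    pattern); level 2 requires at least two diagnostic fragments with
    isomer-discriminating evidence (2a when retention-time support backs a
    single isomer, 2b otherwise); level 3a a single diagnostic fragment.
    """
    if (evidence.standard_rt_match and evidence.standard_ms2_match
            and evidence.isotope_pass):
        return "1"
    if evidence.n_fragments_matched >= 2 and evidence.isomer_discriminating:
        return "2a" if evidence.rt_support else "2b"
    if evidence.n_fragments_matched >= 1:
        return "3a"
    return "rejected"


def _dedup(candidates: list[MatchCandidate], window_min: float) -> list[MatchCandidate]:
    """Collapse duplicates per compound: within an RT cluster of ``window_min``,
    keep the candidate with the smallest |ppm|."""
    out = []
    by_compound: dict[str, list[MatchCandidate]] = {}
    for c in candidates:
        by_compound.setdefault(c.compound.acronym, []).append(c)
    for group in by_compound.values():
        group.sort(key=lambda c: c.rt_min)
        cluster: list[MatchCandidate] = []
        for c in group:
            if cluster and c.rt_min - cluster[-1].rt_min > window_min:
                out.append(min(cluster, key=lambda x: abs(x.ppm)))
                cluster = []
            cluster.append(c)
        if cluster:
            out.append(min(cluster, key=lambda x: abs(x.ppm)))
    return out


def run_screen(
    table: FeatureTable,
    spectra: dict[str, Spectrum],
    suspects: list[CompoundRecord],
    config: ScreenConfig = ScreenConfig(),
    rules: dict[str, list[FragmentRule]] | None = None,
    predicted_rt: dict[str, float] | None = None,
    standards: set[str] | frozenset[str] = frozenset(),
) -> tuple[list[AnnotatedHit], ScreenReport]:
    """Run the full cascade: blank -> mass -> isotope -> RT -> fragments -> CL.

    ``standards`` names suspects backed by authentic standards; their hits
    qualify for level 1 when RT and fragment evidence align.  Duplicate
    matches per compound are collapsed keeping the best mass error; the
    peak-shape stage of the funnel is a pass-through (features arrive
    pre-picked).  Returns the identified hits and the funnel report.
    """
    if rules is None:
        from .chem import load_fragment_rules
        rules = load_fragment_rules()

    report = ScreenReport(raw_peaks=len(table.data))

    survivors = subtract_blank(table, config.blank_factor)
    report.post_blank = len(survivors.data)

    candidates = match_suspects(survivors, suspects, config.tol_ppm_ms1)

    env_of = {
        row.feature_id: (1.0, row.iso_m1, row.iso_m2)
        for row in survivors.data.itertuples(index=False)
    }
    kept = []
    for c in candidates:
        fit = isotope_fit(env_of[c.feature_id], c.compound.anion_formula, config)
        if fit.passed:
            kept.append(replace(c, passed_isotope=True))
    candidates = kept

    candidates = filter_rt(candidates, predicted_rt, config.rt_tol_min,
                           config.rt_missing_policy)
    report.mass_matched = len({c.feature_id for c in candidates})

    candidates = _dedup(candidates, config.dedup_rt_window_min)
    report.post_dedup = len({c.feature_id for c in candidates})

    hits: list[AnnotatedHit] = []
    for c in candidates:
        frags = annotate_fragments(c, spectra.get(c.feature_id), rules,
                                   config.tol_ppm_ms2)
        c = replace(c, passed_fragment=bool(frags))
        # Chain-length-specific ions (templates in n) and precursor-anchored
        # neutral losses pin the homologue, so they count as isomer evidence.
        discriminating = any("n" in f.rule.formula_template
                             or f.rule.kind == "neutral-loss" for f in frags)
        is_standard = c.compound.acronym in standards
        rt_support = c.passed_rt is True and not c.rt_unfiltered
        evidence = Evidence(
            standard_rt_match=is_standard and rt_support,
            standard_ms2_match=is_standard and bool(frags),
            isotope_pass=c.passed_isotope is True,
            n_fragments_matched=len(frags),
            isomer_discriminating=discriminating,
            rt_support=rt_support,
        )
        level = assign_confidence(evidence)
        hits.append(AnnotatedHit(c, tuple(frags), level))

    report.annotated = len({h.candidate.feature_id for h in hits if h.fragments})
    hits = [h for h in hits if h.confidence_level != "rejected"]
    report.identified = len({h.candidate.feature_id for h in hits})
    return hits, report


def hits_to_frame(hits: list[AnnotatedHit]) -> pd.DataFrame:
    """Flatten hits to a DataFrame (one row per annotated hit) for CSV export."""
    rows = [{
        "feature_id": h.candidate.feature_id,
        "compound": h.candidate.compound.acronym,
        "class_id": h.candidate.compound.class_id,
        "observed_mz": h.candidate.observed_mz,
        "rt_min": h.candidate.rt_min,
        "ppm": h.candidate.ppm,
        "n_fragments": len(h.fragments),
        "fragments": ";".join(f.formula for f in h.fragments),
        "confidence_level": h.confidence_level,
    } for h in hits]
    return pd.DataFrame(rows)
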