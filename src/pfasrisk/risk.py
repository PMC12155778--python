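"""Exposure-weighted risk prioritization of identified compounds.

Hazard (the ToxPi score) is combined with drinking-water occurrence through

    Magnitude_i   = (C_i - C_min) / (C_max - C_min)
    Exposure_i    = DF_i x Magnitude_i
    Exposure_norm = min-max of Exposure over the compound set
    RI_i          = ToxPi_i x Exposure_norm_i

where C_i is the compound's maximum concentration across samples (ng/L) and
DF_i its detection frequency.  Reference pseudo-compounds (ref-PFOA,
ref-PFOS) are anchored at the US EPA Maximum Contaminant Level of 4 ng/L
with DF = 1 and pushed through the same equations using the real set's
normalization constants; compounds whose RI strictly exceeds both reference
RIs are flagged high-concern.

An alternative reading bins concentration and detection frequency into five
ordered categories before Eqs.; ``compute_exposures(..., binned=True)``
implements it, the continuous form is the default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chem import CompoundRecord

__all__ = [
    "compute_exposures",
    "risk_index",
    "combine_risk",
    "reference_indices",
    "rank_and_flag",
    "legacy_share",
    "MCL_NG_L",
]

#: US EPA Maximum Contaminant Level for PFOA and PFOS, ng/L.
MCL_NG_L = 4.0


def _bin_ordinal(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile-bin to ordered categories mapped onto [0, 1]."""
    ranks = pd.Series(values).rank(method="average", pct=True).to_numpy()
    bins = np.minimum((ranks * n_bins).astype(int), n_bins - 1)
    return bins / (n_bins - 1)


def compute_exposures(
    occurrence: pd.DataFrame,
    binned: bool = False,
    n_bins: int = 5,
) -> pd.DataFrame:
    """Magnitude, Exposure and normalized Exposure per compound.

    ``occurrence`` is indexed by compound with columns
    ``detection_frequency`` (fraction) and ``max_concentration`` (ng/L).
    Normalization constants are taken over the supplied set, which must
    contain at least two distinct concentrations.
    """
    required = {"detection_frequency", "max_concentration"}
    if not required.issubset(occurrence.columns):
        raise ValueError(f"occurrence table needs columns {sorted(required)}")
    if len(occurrence) < 2:
        raise ValueError("need at least two compounds")
    c = occurrence["max_concentration"].to_numpy(dtype=float)
    df = occurrence["detection_frequency"].to_numpy(dtype=float)
    if np.all(c == c[0]):
        raise ValueError("all concentrations equal: min-max normalization degenerate")
    if binned:
        magnitude = _bin_ordinal(c, n_bins)
        df = _bin_ordinal(df, n_bins)
    else:
        magnitude = (c - c.min()) / (c.max() - c.min())
    exposure = df * magnitude
    span = exposure.max() - exposure.min()
    exposure_norm = (exposure - exposure.min()) / span if span > 0 else exposure * 0.0
    out = occurrence[["detection_frequency", "max_concentration"]].copy()
    out["magnitude"] = magnitude
    out["exposure"] = exposure
    out["exposure_normalized"] = exposure_norm
    return out


def risk_index(toxpi_score: float, exposure_normalized: float) -> float:
    """RI = ToxPi x normalized exposure; both factors must be in [0, 1]."""
    for name, v in (("toxpi_score", toxpi_score),
                    ("exposure_normalized", exposure_normalized)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} outside [0, 1]: {v}")
    return float(toxpi_score) * float(exposure_normalized)


def combine_risk(exposures: pd.DataFrame, toxpi: pd.Series) -> pd.DataFrame:
    """Join exposure records with ToxPi scores and compute per-compound RIs."""
    missing = exposures.index.difference(toxpi.index)
    if len(missing):
        raise ValueError(f"no ToxPi score for: {missing.tolist()}")
    out = exposures.copy()
    out["toxpi"] = toxpi.reindex(out.index).astype(float)
    out["ri"] = [risk_index(t, e) for t, e in
                 zip(out["toxpi"], out["exposure_normalized"])]
    out["reference"] = False
    return out


def reference_indices(
    toxpi: pd.Series,
    occurrence: pd.DataFrame,
    ref_conc: float = MCL_NG_L,
    ref_df: float = 1.0,
    bases: tuple[str, ...] = ("PFOA", "PFOS"),
) -> pd.DataFrame:
    """MCL-anchored reference pseudo-compounds run through the same equations.

    Each reference inherits the ToxPi score of its base compound, sits at
    ``ref_conc`` ng/L with detection frequency ``ref_df``, and is normalized
    with the real set's C_min/C_max and exposure extremes (references are
    excluded from those constants).
    """
    missing = [b for b in bases if b not in toxpi.index]
    if missing:
        raise ValueError(f"no ToxPi score for reference base compounds: {missing}")
    real = compute_exposures(occurrence)
    c = occurrence["max_concentration"].to_numpy(dtype=float)
    c_min, c_max = c.min(), c.max()
    magnitude = (ref_conc - c_min) / (c_max - c_min)
    exposure = ref_df * magnitude
    e = real["exposure"].to_numpy()
    span = e.max() - e.min()
    exposure_norm = (exposure - e.min()) / span if span > 0 else 0.0
    rows = {}
    for base in bases:
        rows[f"ref-{base}"] = {
            "detection_frequency": ref_df,
            "max_concentration": ref_conc,
            "magnitude": magnitude,
            "exposure": exposure,
            "exposure_normalized": exposure_norm,
            "toxpi": float(toxpi[base]),
            "ri": risk_index(float(toxpi[base]), float(np.clip(exposure_norm, 0, 1))),
            "reference": True,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "compound"
    return out


def rank_and_flag(risk_results: pd.DataFrame, references: pd.DataFrame) -> pd.DataFrame:
    """Descending-RI priority list with high-concern flags.

    High-concern compounds have RI strictly above the larger of the two
    reference RIs.  Ties are broken by ToxPi score, then alphabetically, so
    the ordering is invariant to input permutation.
    """
    threshold = references["ri"].max()
    out = pd.concat([risk_results, references])
    out.index.name = "compound"
    out["high_concern"] = (~out["reference"]) & (out["ri"] > threshold)
    # mergesort over (alphabetical, ToxPi, RI) -> stable descending-RI order
    # with ToxPi-then-alphabetical tie-breaks
    out = (out.reset_index()
              .sort_values("compound", kind="mergesort")
              .sort_values("toxpi", ascending=False, kind="mergesort")
              .sort_values("ri", ascending=False, kind="mergesort")
              .set_index("compound"))
    return out


def legacy_share(registry: list[CompoundRecord]) -> int:
    """Percent of the summed maximum concentrations carried by legacy
    compounds, rounded to an integer for reporting."""
    total = sum(r.max_concentration for r in registry)
    if total <= 0:
        raise ValueError("total maximum concentration is zero")
    legacy = sum(r.max_concentration for r in registry if r.legacy)
    return int(round(100.0 * legacy / total))
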