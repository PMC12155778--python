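"""Target quantification, RF-based semi-quantification and occurrence summaries.

Targets with authentic standards are quantified from internal-standard-
normalized calibration curves (ordinary least squares, QC rule r^2 > 0.99).
Suspects without standards are semi-quantified as response / predicted RF
with the intercept assumed zero.  Per-compound occurrence is summarized as
the detection frequency (fraction of samples at or above the LOQ) and the
maximum concentration, the two quantities the risk module consumes.

Censored (<LOQ) values contribute 0 to detection frequency and summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Calibration",
    "Measurement",
    "fit_calibration",
    "quantify_target",
    "semiquantify",
    "summarize_occurrence",
]


@dataclass(frozen=True)
class Calibration:
    """A fitted concentration-response line for one compound."""

    compound: str
    levels: tuple[float, ...]     # ng/L
    responses: tuple[float, ...]  # IS-normalized
    slope: float                  # the response factor
    intercept: float
    r2: float
    lod: float                    # ng/L
    loq: float                    # ng/L
    qc_pass: bool                 # r^2 > 0.99


@dataclass(frozen=True)
class Measurement:
    """A single quantified concentration with censoring status."""

    concentration: float  # ng/L; raw estimate even when censored
    censored: bool        # True when below the LOQ

    @property
    def reported(self) -> float:
        """Value used in summaries: 0 when censored."""
        return 0.0 if self.censored else self.concentration

    def __str__(self) -> str:
        return "<LOQ" if self.censored else f"{self.concentration:g}"


def fit_calibration(
    levels,
    responses,
    compound: str = "",
    lod: float | None = None,
    loq: float | None = None,
) -> Calibration:
    """OLS calibration over >= 5 strictly increasing levels.

    When detection limits are not supplied they are estimated from the fit
    residuals (LOD = 3.3 s/slope, LOQ = 10 s/slope, the usual
    residual-SD-based rule).
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(x) < 5:
        raise ValueError(f"need >= 5 calibration levels, got {len(x)}")
    if len(x) != len(y):
        raise ValueError("levels and responses length mismatch")
    if not np.all(np.diff(x) > 0):
        raise ValueError("calibration levels must be strictly increasing")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue ** 2)
    resid = y - (fit.intercept + fit.slope * x)
    s = float(np.sqrt(np.sum(resid ** 2) / max(len(x) - 2, 1)))
    if fit.slope != 0:
        lod = lod if lod is not None else 3.3 * s / abs(fit.slope)
        loq = loq if loq is not None else 10.0 * s / abs(fit.slope)
    else:
        lod = lod if lod is not None else float("inf")
        loq = loq if loq is not None else float("inf")
    return Calibration(
        compound=compound,
        levels=tuple(map(float, x)),
        responses=tuple(map(float, y)),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        lod=float(lod),
        loq=float(loq),
        qc_pass=r2 > 0.99,
    )


def quantify_target(response: float, calibration: Calibration) -> Measurement:
    """Invert the calibration line; flag results below the LOQ as censored."""
    if calibration.slope <= 0:
        raise ValueError(
            f"calibration for {calibration.compound or '?'} has non-positive slope")
    conc = (response - calibration.intercept) / calibration.slope
    return Measurement(concentration=float(conc), censored=conc < calibration.loq)


def semiquantify(response: float, predicted_rf: float) -> float:
    """Concentration = response / predicted RF (zero intercept for
    standard-free compounds)."""
    if predicted_rf <= 0:
        raise ValueError(f"predicted RF must be positive, got {predicted_rf}")
    return float(response) / float(predicted_rf)


def summarize_occurrence(
    concentrations: pd.DataFrame,
    loqs: dict[str, float] | pd.Series | float = 0.0,
) -> pd.DataFrame:
    """Per-compound detection frequency and maximum concentration.

    ``concentrations`` is samples x compounds (ng/L); censored cells may be
    NaN or any value below the compound's LOQ — both count as non-detects
    and contribute 0.  Returns a frame indexed by compound with columns
    ``detection_frequency`` (fraction of samples >= LOQ) and
    ``max_concentration``.  Invariant to sample ordering.
    """
    if concentrations.shape[0] == 0:
        raise ValueError("no samples to summarize")
    if isinstance(loqs, (int, float)):
        loq_of = {c: float(loqs) for c in concentrations.columns}
    else:
        loq_of = dict(pd.Series(loqs))
    rows = {}
    n = len(concentrations)
    for comp in concentrations.columns:
        vals = concentrations[comp].to_numpy(dtype=float)
        loq = loq_of.get(comp, 0.0)
        detected = np.where(np.isnan(vals), False, vals >= max(loq, 1e-300))
        reported = np.where(detected, vals, 0.0)
        rows[comp] = {
            "detection_frequency": float(detected.sum()) / n,
            "max_concentration": float(reported.max()) if n else 0.0,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "compound"
    return out
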