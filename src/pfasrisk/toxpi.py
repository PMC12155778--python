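"""ToxPi hazard scoring from a compound x attribute table.

Each raw attribute (a QSAR or docking output supplied as input data) is
first put on a "larger = more hazardous" scale by its transform — negation
for biodegradation probabilities (faster degradation is less hazardous),
-log10 for lethal/effective doses (a lower dose is more toxic), log10 for
bioaccumulation factors, identity otherwise — then min-max normalized across
the scored compound set, weighted, and combined:

    ToxPi_i = W_p * P_i + W_b * B_i + W_t * T_i

with P, B, T the persistence, bioaccumulation and toxicity slice scores
(weight-weighted means within their attribute groups, each in [0, 1]) and
W_g the group weight sums.  The printed per-attribute weights sum to 46/45
rather than 1; by default the weights are renormalized by their total so
scores land in [0, 1], and ``audit_weights`` surfaces the discrepancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "AttributeSpec",
    "GROUPS",
    "SLICE_OF_GROUP",
    "load_attribute_specs",
    "scale_attribute",
    "normalize_slice",
    "audit_weights",
    "toxpi_scores",
]

GROUPS = ("persistence", "bioaccumulation", "ecotox", "human-health", "docking")

#: The three pie slices; toxicity pools ecotox, human-health and docking.
SLICE_OF_GROUP = {
    "persistence": "P",
    "bioaccumulation": "B",
    "ecotox": "T",
    "human-health": "T",
    "docking": "T",
}

_TRANSFORMS = ("x", "-x", "log10(x)", "-log10(x)")


@dataclass(frozen=True)
class AttributeSpec:
    """One hazard attribute: group membership, scaling transform and weight."""

    attribute: str
    group: str
    unit: str
    scaling: str
    weight: Fraction

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"{self.attribute}: unknown group {self.group!r}")
        if self.scaling not in _TRANSFORMS:
            raise ValueError(f"{self.attribute}: unknown scaling {self.scaling!r}")
        if self.weight <= 0:
            raise ValueError(f"{self.attribute}: weight must be positive")


def load_attribute_specs(path=None) -> list[AttributeSpec]:
    """Load the attribute specification TSV; packaged 19-attribute table by
    default (3 persistence + 2 bioaccumulation + 3 ecotox + 5 human-health
    + 6 docking)."""
    if path is None:
        path = resources.files("pfasrisk.data") / "toxpi_attributes.tsv"
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        AttributeSpec(
            attribute=row["attribute"],
            group=row["group"],
            unit=row["unit"],
            scaling=row["scaling"],
            weight=Fraction(row["weight"]),
        )
        for _, row in df.iterrows()
    ]


def scale_attribute(values: pd.Series, transform: str) -> pd.Series:
    """Apply a scaling transform elementwise; log transforms require x > 0.

    Offending compounds are named in the error when a non-positive value
    meets a log transform.
    """
    v = values.astype(float)
    if transform == "x":
        return v
    if transform == "-x":
        return -v
    if transform in ("log10(x)", "-log10(x)"):
        bad = v.index[~(v > 0)].tolist()
        if bad:
            raise ValueError(
                f"non-positive value under {transform} for compounds: {bad}")
        out = np.log10(v)
        return -out if transform.startswith("-") else out
    raise ValueError(f"unknown transform {transform!r}")


def normalize_slice(values: pd.Series) -> pd.Series:
    """Min-max normalize across compounds; a constant attribute maps to all 0."""
    v = values.astype(float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return pd.Series(0.0, index=v.index)
    return (v - lo) / (hi - lo)


def audit_weights(specs: list[AttributeSpec]) -> dict:
    """Exact rational weight sums per group and total; warns when total != 1."""
    if not specs:
        raise ValueError("empty attribute specification")
    group_sums: dict[str, Fraction] = {}
    for s in specs:
        group_sums[s.group] = group_sums.get(s.group, Fraction(0)) + s.weight
    total = sum(group_sums.values(), Fraction(0))
    if total != 1:
        warnings.warn(
            f"attribute weights sum to {total} (= {float(total):.4f}), not 1; "
            f"renormalization divides by this total")
    return {
        "group_sums": group_sums,
        "total": total,
        "renormalization_factor": Fraction(1) / total,
    }


def toxpi_scores(
    attribute_table: pd.DataFrame,
    specs: list[AttributeSpec] | None = None,
    renormalize: bool = True,
) -> pd.DataFrame:
    """Slice and total ToxPi scores for every compound in the table.

    ``attribute_table`` is compounds x raw attribute values and must contain
    every spec attribute.  Returns a frame indexed by compound with columns
    P, B, T (slice scores, each in [0, 1]) and ``toxpi`` (the weighted
    total; in [0, 1] when ``renormalize`` is on).
    """
    if specs is None:
        specs = load_attribute_specs()
    missing = [s.attribute for s in specs if s.attribute not in attribute_table.columns]
    if missing:
        raise ValueError(f"attribute table missing columns: {missing}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        audit = audit_weights(specs)
    total_weight = audit["total"]

    normed = {}
    for s in specs:
        transformed = scale_attribute(attribute_table[s.attribute], s.scaling)
        normed[s.attribute] = normalize_slice(transformed)

    index = attribute_table.index
    slice_num = {sl: pd.Series(0.0, index=index) for sl in ("P", "B", "T")}
    slice_den = {sl: Fraction(0) for sl in ("P", "B", "T")}
    total = pd.Series(0.0, index=index)
    for s in specs:
        sl = SLICE_OF_GROUP[s.group]
        w = float(s.weight)
        slice_num[sl] = slice_num[sl] + w * normed[s.attribute]
        slice_den[sl] += s.weight
        eff_w = s.weight / total_weight if renormalize else s.weight
        total = total + float(eff_w) * normed[s.attribute]

    out = pd.DataFrame(index=index)
    for sl in ("P", "B", "T"):
        den = float(slice_den[sl])
        out[sl] = slice_num[sl] / den if den > 0 else 0.0
    out["toxpi"] = total
    out.index.name = "compound"
    return out
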