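"""Elemental-mass chemistry for PFAS suspect screening.

Molecular-formula arithmetic, monoisotopic and anion m/z computation,
homologue-series formula rules for the eleven PFAS classes encountered in
drinking water, class-specific diagnostic-fragment rules, and the packaged
compound registry of the 30 identified PFASs.

All formulas are element-count maps over {C, H, N, O, F, S, Cl}; no
structures, SMILES or geometry are handled here.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "ALLOWED_ELEMENTS",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "ElementCounts",
    "CompoundRecord",
    "FragmentRule",
    "parse_formula",
    "monoisotopic_mass",
    "anion_mz",
    "deprotonated",
    "ppm_error",
    "homologue_formula",
    "isotope_envelope",
    "load_registry",
    "load_fragment_rules",
    "registry_summary",
    "PFAS_CLASSES",
]

# Lightest-isotope masses (Da), CODATA/IUPAC monoisotopic values.  Kept in a
# single table so tests can pin them.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250,
    "C": 12.0,
    "N": 14.0030740,
    "O": 15.9949146,
    "F": 18.9984032,
    "S": 31.9720707,
    "Cl": 34.9688527,
}

ELECTRON_MASS = 0.0005486  # Da

ALLOWED_ELEMENTS = frozenset(MONOISOTOPIC_MASS)

# Isotope abundance patterns by nominal mass offset (+0, +1, +2) relative to
# the lightest isotope.  Used for the M/M+1/M+2 envelope model.
_ISOTOPE_PATTERN: dict[str, tuple[float, ...]] = {
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "F": (1.0,),
    "S": (0.9499, 0.0075, 0.0425),
    "Cl": (0.7576, 0.0, 0.2424),
}

#: The eleven PFAS classes of the drinking-water registry.
PFAS_CLASSES = (
    "PFCA", "PFSA", "PFdiOA", "H-PFCA", "H-PFSA", "PFECA",
    "FTSA", "Cl-PFESA", "H-PFESA", "PFSM", "HNTf2",
)

_CONFIDENCE_LEVELS = ("1", "2a", "2b", "3a")


class ElementCounts(Mapping[str, int]):
    """Immutable element → count map restricted to {C,H,N,O,F,S,Cl}.

    At least one element must have a count >= 1; zero counts are dropped.
    """

    __slots__ = ("_counts",)

    # Hill-like ordering for canonical text: C, H, then alphabetical.
    _ORDER = ("C", "H", "Cl", "F", "N", "O", "S")

    def __init__(self, counts: Mapping[str, int]):
        clean: dict[str, int] = {}
        for el, n in counts.items():
            if el not in ALLOWED_ELEMENTS:
                raise ValueError(f"unknown element symbol: {el!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
            if n:
                clean[el] = n
        if not clean:
            raise ValueError("formula must contain at least one atom")
        self._counts = clean

    def __getitem__(self, el: str) -> int:
        return self._counts[el]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other) -> bool:
        if isinstance(other, ElementCounts):
            return self._counts == other._counts
        return dict(self) == dict(other) if isinstance(other, Mapping) else NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        return f"ElementCounts({self.canonical()!r})"

    def canonical(self) -> str:
        """Canonical text: C first, H second, remaining elements alphabetical."""
        parts = []
        for el in self._ORDER:
            n = self._counts.get(el, 0)
            if n:
                parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def add(self, other: Mapping[str, int]) -> "ElementCounts":
        c = Counter(self._counts)
        c.update(other)
        return ElementCounts(c)

    def subtract(self, other: Mapping[str, int]) -> "ElementCounts":
        c = Counter(self._counts)
        c.subtract(other)
        if any(v < 0 for v in c.values()):
            raise ValueError(f"cannot subtract {dict(other)} from {self.canonical()}")
        return ElementCounts(c)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementCounts:
    """Parse a molecular formula string such as ``"C4HF9O3S"``.

    Element symbols are one capital letter optionally followed by one
    lowercase letter; counts are optional (default 1).  Unknown symbols are
    rejected by name.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    pos = 0
    counts: Counter[str] = Counter()
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in ALLOWED_ELEMENTS:
            raise ValueError(f"unknown element symbol: {el!r} in {text!r}")
        counts[el] += int(num) if num else 1
        pos = m.end()
    return ElementCounts(counts)


def monoisotopic_mass(f: Mapping[str, int]) -> float:
    """Monoisotopic (lightest-isotope) mass in Da."""
    if not isinstance(f, ElementCounts):
        f = ElementCounts(f)
    return sum(n * MONOISOTOPIC_MASS[el] for el, n in f.items())


def anion_mz(f: Mapping[str, int], charge: int = 1) -> float:
    """m/z of the anion with formula ``f`` carrying ``charge`` extra electrons.

    The electron mass is added per charge: [SO3]- at 79.95736, not 79.95681.
    """
    charge = int(charge)
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (monoisotopic_mass(f) + charge * ELECTRON_MASS) / charge


def deprotonated(f: Mapping[str, int]) -> ElementCounts:
    """Formula of the [M-H]- anion of a neutral acid."""
    if not isinstance(f, ElementCounts):
        f = ElementCounts(f)
    return f.subtract({"H": 1})


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


# --------------------------------------------------------------------------
# Homologue series
#
# Each class maps a carbon count n (the registry's N column, total carbons)
# to the neutral-acid formula.  Coefficients are (a, b) meaning count = a*n+b.
_HOMOLOGUE_RULES: dict[str, tuple[dict[str, tuple[int, int]], range]] = {
    # CnHF(2n-1)O2, perfluorocarboxylic acids C3-C12
    "PFCA": ({"C": (1, 0), "H": (0, 1), "F": (2, -1), "O": (0, 2)}, range(3, 13)),
    # CnHF(2n+1)SO3, perfluorosulfonic acids C3-C8
    "PFSA": ({"C": (1, 0), "H": (0, 1), "F": (2, 1), "O": (0, 3), "S": (0, 1)}, range(3, 9)),
    # HOOC(CF2)(n-2)COOH
    "PFdiOA": ({"C": (1, 0), "H": (0, 2), "F": (2, -4), "O": (0, 4)}, range(4, 16)),
    # one F of the PFCA replaced by H
    "H-PFCA": ({"C": (1, 0), "H": (0, 2), "F": (2, -2), "O": (0, 2)}, range(4, 7)),
    # one F of the PFSA replaced by H
    "H-PFSA": ({"C": (1, 0), "H": (0, 2), "F": (2, 0), "O": (0, 3), "S": (0, 1)}, range(4, 7)),
    # perfluoroether carboxylic acids (one ether O): CnHF(2n-1)O3
    "PFECA": ({"C": (1, 0), "H": (0, 1), "F": (2, -1), "O": (0, 3)}, range(3, 9)),
    # x:2 fluorotelomer sulfonic acids, n = x+2 total carbons
    "FTSA": ({"C": (1, 0), "H": (0, 5), "F": (2, -3), "O": (0, 3), "S": (0, 1)}, range(4, 11)),
    # chlorinated perfluoroether sulfonates, e.g. 6:2 Cl-PFESA at n=8
    "Cl-PFESA": ({"C": (1, 0), "H": (0, 1), "Cl": (0, 1), "F": (2, 0), "O": (0, 4), "S": (0, 1)}, range(8, 11)),
    # hydrogenated perfluoroether sulfonates
    "H-PFESA": ({"C": (1, 0), "H": (0, 2), "F": (2, 0), "O": (0, 4), "S": (0, 1)}, range(4, 7)),
    # sulfonamidoacetic acids, e.g. FBSAA at n=6
    "PFSM": ({"C": (1, 0), "H": (0, 4), "F": (2, -3), "N": (0, 1), "O": (0, 4), "S": (0, 1)}, range(5, 11)),
    # bis(trifluoromethanesulfonyl)imide, the single n=2 member
    "HNTf2": ({"C": (1, 0), "H": (0, 1), "F": (2, 2), "N": (0, 1), "O": (0, 4), "S": (0, 2)}, range(2, 3)),
}


def homologue_formula(class_id: str, n_carbons: int) -> ElementCounts:
    """Neutral-acid formula of the class homologue with ``n_carbons`` carbons.

    Raises ``ValueError`` for an unknown class or a carbon count outside the
    class's observed range.
    """
    if class_id not in _HOMOLOGUE_RULES:
        raise ValueError(f"unknown or non-parameterizable class: {class_id!r}")
    coeffs, valid = _HOMOLOGUE_RULES[class_id]
    n = int(n_carbons)
    if n not in valid:
        raise ValueError(
            f"{class_id} homologue with n={n} outside supported range "
            f"[{valid.start}, {valid.stop - 1}]"
        )
    return ElementCounts({el: a * n + b for el, (a, b) in coeffs.items()})


# --------------------------------------------------------------------------
# Isotope envelope

def isotope_envelope(f: Mapping[str, int], n_peaks: int = 3) -> list[float]:
    """Relative M, M+1, ... M+(n_peaks-1) abundances, normalized to M = 1.

    Aggregated per nominal-mass offset: the per-atom isotope pattern of each
    element is convolved atom by atom and truncated at the requested offset.
    """
    if not isinstance(f, ElementCounts):
        f = ElementCounts(f)
    pattern = [1.0] + [0.0] * (n_peaks - 1)
    for el, count in f.items():
        atom = list(_ISOTOPE_PATTERN[el])[:n_peaks]
        atom += [0.0] * (n_peaks - len(atom))
        for _ in range(count):
            out = [0.0] * n_peaks
            for i in range(n_peaks):
                if pattern[i] == 0.0:
                    continue
                for j in range(n_peaks - i):
                    out[i + j] += pattern[i] * atom[j]
            pattern = out
    if pattern[0] <= 0:
        raise ValueError("degenerate isotope pattern")
    return [p / pattern[0] for p in pattern]


# --------------------------------------------------------------------------
# Registry and fragment rules

@dataclass(frozen=True)
class CompoundRecord:
    """One registry entry: an identified PFAS with occurrence summary."""

    acronym: str
    class_id: str
    n_carbons: int
    formula: ElementCounts
    confidence_level: str
    detection_frequency: float  # fraction in [0, 1]
    max_concentration: float    # ng/L
    legacy: bool

    def __post_init__(self):
        if self.class_id not in PFAS_CLASSES:
            raise ValueError(f"{self.acronym}: unknown class {self.class_id!r}")
        if self.confidence_level not in _CONFIDENCE_LEVELS:
            raise ValueError(f"{self.acronym}: bad confidence level {self.confidence_level!r}")
        if not 0.0 <= self.detection_frequency <= 1.0:
            raise ValueError(f"{self.acronym}: DF outside [0,1]: {self.detection_frequency}")
        if self.max_concentration < 0:
            raise ValueError(f"{self.acronym}: negative max concentration")

    @property
    def anion_formula(self) -> ElementCounts:
        return deprotonated(self.formula)

    @property
    def theoretical_mz(self) -> float:
        return anion_mz(self.anion_formula)


@dataclass(frozen=True)
class FragmentRule:
    """A class-diagnostic MS2 fragment: an anion fragment or a neutral loss.

    ``formula_template`` may be parameterized in the homologue carbon count n
    (e.g. ``"C{n}F{2n+1}"``); :meth:`resolve` substitutes a concrete n.
    """

    class_id: str
    kind: str  # "anion-fragment" | "neutral-loss"
    formula_template: str
    required: bool

    def __post_init__(self):
        if self.kind not in ("anion-fragment", "neutral-loss"):
            raise ValueError(f"bad fragment kind: {self.kind!r}")

    def resolve(self, n_carbons: int) -> ElementCounts:
        """Instantiate the template for a homologue with ``n_carbons`` carbons."""
        return _resolve_template(self.formula_template, n_carbons)


_TEMPLATE_TOKEN = re.compile(r"([A-Z][a-z]?)(\{[^}]*\}|\d*)")
_LINEAR_EXPR = re.compile(r"^\s*(?:(\d*)n\s*)?([+-]?\s*\d+)?\s*$")


def _resolve_template(template: str, n: int) -> ElementCounts:
    pos = 0
    counts: Counter[str] = Counter()
    while pos < len(template):
        m = _TEMPLATE_TOKEN.match(template, pos)
        if not m or m.start() != pos:
            raise ValueError(f"cannot parse fragment template {template!r}")
        el, spec = m.group(1), m.group(2)
        if spec.startswith("{"):
            expr = spec[1:-1]
            lm = _LINEAR_EXPR.match(expr)
            if not lm or (lm.group(1) is None and lm.group(2) is None):
                raise ValueError(f"bad count expression {expr!r} in {template!r}")
            if "n" in expr:
                a = int(lm.group(1)) if lm.group(1) else 1
                b = int(lm.group(2).replace(" ", "")) if lm.group(2) else 0
            else:
                a, b = 0, int(lm.group(2).replace(" ", ""))
            count = a * n + b
        else:
            count = int(spec) if spec else 1
        if count < 0:
            raise ValueError(f"template {template!r} gives negative {el} count at n={n}")
        counts[el] += count
        pos = m.end()
    return ElementCounts(counts)


def _registry_path():
    return resources.files("pfasrisk.data") / "registry.tsv"


def _fragment_rules_path():
    return resources.files("pfasrisk.data") / "fragment_rules.tsv"


_REGISTRY_COLUMNS = [
    "acronym", "class_id", "n_carbons", "formula", "confidence_level",
    "detection_frequency_pct", "max_conc_ng_L", "legacy",
]


def load_registry(path=None) -> list[CompoundRecord]:
    """Load a compound registry TSV; defaults to the packaged 30-compound table.

    Detection frequencies are converted from printed percentages to fractions
    at parse time.  Rows violating the record invariants are rejected with
    their row number.
    """
    if path is None:
        path = _registry_path()
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry missing required columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(CompoundRecord(
                acronym=row["acronym"],
                class_id=row["class_id"],
                n_carbons=int(row["n_carbons"]),
                formula=parse_formula(row["formula"]),
                confidence_level=str(row["confidence_level"]),
                detection_frequency=float(row["detection_frequency_pct"]) / 100.0,
                max_concentration=float(row["max_conc_ng_L"]),
                legacy=str(row["legacy"]).strip().lower() in ("true", "1", "yes"),
            ))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"registry row {i + 2}: {exc}") from exc
    return records


def load_fragment_rules(path=None) -> dict[str, list[FragmentRule]]:
    """Load diagnostic-fragment rules grouped by class; packaged table by default."""
    if path is None:
        path = _fragment_rules_path()
    df = pd.read_csv(path, sep="\t", dtype=str)
    rules: dict[str, list[FragmentRule]] = {}
    for _, row in df.iterrows():
        rule = FragmentRule(
            class_id=row["class_id"],
            kind=row["kind"],
            formula_template=row["formula_template"],
            required=str(row["required"]).strip().lower() in ("true", "1", "yes"),
        )
        rules.setdefault(rule.class_id, []).append(rule)
    return rules


def registry_summary(records: list[CompoundRecord]) -> dict:
    """Counts by class, legacy/novel and confidence level."""
    if not records:
        warnings.warn("registry_summary called with an empty record list")
        return {"n_compounds": 0, "by_class": {}, "legacy": 0, "novel": 0,
                "by_confidence_level": {}}
    by_class: Counter[str] = Counter(r.class_id for r in records)
    by_cl: Counter[str] = Counter(r.confidence_level for r in records)
    legacy = sum(r.legacy for r in records)
    return {
        "n_compounds": len(records),
        "by_class": dict(by_class),
        "legacy": legacy,
        "novel": len(records) - legacy,
        "by_confidence_level": dict(by_cl),
    }
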