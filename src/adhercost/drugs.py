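"""Drug-class mapping and DDD (defined daily dose) resolution.

The four guideline-recommended drug classes after acute myocardial infarction
are identified by ATC prefix: anti-platelet agents (B01A), statins (C10),
beta-blockers (C07), and ACE inhibitors (C09A, C09B).

Dispensed mass is converted to days of supply by dividing by the DDD in
mg/day.  The DDD table is layered: a base layer (WIdO/WHO-style values) and
an override layer holding guideline dosages that replace the base value where
the two disagree.  The shipped override layer contains the nine ACE-inhibitor
and statin adjustments used in the source analysis (e.g. ramipril 10 mg
instead of 2.5 mg).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

#: Canonical drug-class identifiers.
DRUG_CLASSES = ("ACE", "BB", "STATIN", "APA")

#: ATC prefixes defining each class.
ATC_PREFIXES = {
    "ACE": ("C09A", "C09B"),
    "BB": ("C07",),
    "STATIN": ("C10",),
    "APA": ("B01A",),
}

#: Human-readable labels used in reports.
CLASS_LABELS = {
    "ACE": "ACE inhibitors",
    "BB": "beta-blockers",
    "STATIN": "statins",
    "APA": "anti-platelet agents",
}


def classify_atc(atc_code: str) -> str | None:
    """Map an ATC code to one of the four drug classes, or None.

    Codes outside the four classes are not an error: they are simply not
    part of the adherence computation.
    """
    code = str(atc_code).strip().upper()
    for cls, prefixes in ATC_PREFIXES.items():
        if code.startswith(prefixes):
            return cls
    return None


class DddLookupError(KeyError):
    """Raised when an ATC code cannot be resolved to a DDD."""


@dataclass
class DddTable:
    """Layered ATC -> DDD (mg/day) lookup: overrides win over the base layer."""

    base: dict[str, float] = field(default_factory=dict)
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for layer in (self.base, self.overrides):
            for code, ddd in layer.items():
                if not ddd > 0:
                    raise ValueError(f"DDD for {code} must be > 0, got {ddd}")

    @classmethod
    def from_frames(cls, base: pd.DataFrame, overrides: pd.DataFrame | None = None) -> "DddTable":
        def to_map(df: pd.DataFrame) -> dict[str, float]:
            return {str(c).strip().upper(): float(d) for c, d in zip(df["atc_code"], df["ddd_mg"])}

        return cls(base=to_map(base), overrides=to_map(overrides) if overrides is not None else {})

    @classmethod
    def from_csvs(cls, base_path, overrides_path=None) -> "DddTable":
        base = pd.read_csv(base_path)
        overrides = pd.read_csv(overrides_path) if overrides_path is not None else None
        return cls.from_frames(base, overrides)

    @classmethod
    def default(cls) -> "DddTable":
        """Table shipped with the package (base subset + the nine overrides)."""
        root = importlib.resources.files("adhercost") / "data"
        with importlib.resources.as_file(root / "ddd_base.csv") as b, \
                importlib.resources.as_file(root / "ddd_overrides.csv") as o:
            return cls.from_csvs(b, o)

    def resolve(self, atc_code: str) -> float:
        """DDD in mg/day for a code; the override layer wins."""
        code = str(atc_code).strip().upper()
        if code in self.overrides:
            return self.overrides[code]
        if code in self.base:
            return self.base[code]
        raise DddLookupError(f"no DDD known for ATC code {code!r}")

    def days_supplied(self, amount_mg: float, atc_code: str) -> float:
        """Days of supply for a dispensed mass: amount / DDD, fractional."""
        return float(amount_mg) / self.resolve(atc_code)
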