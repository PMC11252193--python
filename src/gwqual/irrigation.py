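"""Irrigation suitability indices and diagram classes.

Seven meq/L-based indices — sodium percent (Na%), sodium adsorption ratio
(SAR), residual sodium carbonate (RSC), Kelley index (KI), permeability
index (PI), magnesium hazard (MH), potential salinity (PS) — plus the
USSL salinity/sodicity class (C1–C4 × S1–S4) and the Wilcox EC–Na% class.

All index functions take meq/L inputs; :func:`assess` performs the single
mg/L→meq/L conversion from a :class:`~gwqual.chemistry.WaterSample`.
Category boundary ties go to the lower band (closed-left convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .chemistry import UndefinedRatioError, WaterSample

__all__ = [
    "IrrigationAssessment",
    "na_percent",
    "sar",
    "rsc",
    "kelley_index",
    "permeability_index",
    "magnesium_hazard",
    "potential_salinity",
    "ussl_class",
    "wilcox_class",
    "WILCOX_BOUNDARIES",
    "categorize",
    "assess",
    "irrigation_table",
    "CATEGORY_TABLES",
]


def na_percent(na: float, k: float, ca: float, mg: float) -> float:
    """Na% = (Na + K) / (Ca + Mg + Na + K) × 100, all meq/L."""
    denom = ca + mg + na + k
    if denom <= 0:
        raise UndefinedRatioError("all cations zero")
    return (na + k) / denom * 100.0


def sar(na: float, ca: float, mg: float) -> float:
    """SAR = Na / sqrt((Ca + Mg) / 2), meq/L."""
    if ca + mg <= 0:
        raise UndefinedRatioError("Ca + Mg must be positive")
    return na / math.sqrt((ca + mg) / 2.0)


def rsc(hco3: float, co3: float, ca: float, mg: float) -> float:
    """RSC = (HCO3 + CO3) − (Ca + Mg), meq/L (signed)."""
    return (hco3 + co3) - (ca + mg)


def kelley_index(na: float, ca: float, mg: float) -> float:
    """KI = Na / (Ca + Mg); suitable below 1."""
    if ca + mg <= 0:
        raise UndefinedRatioError("Ca + Mg must be positive")
    return na / (ca + mg)


def permeability_index(na: float, ca: float, mg: float, hco3: float) -> float:
    """PI = (Na + sqrt(HCO3)) / (Ca + Mg + Na) × 100; can exceed 100 for
    Na-poor, bicarbonate-rich waters."""
    denom = ca + mg + na
    if denom <= 0:
        raise UndefinedRatioError("Ca + Mg + Na must be positive")
    if hco3 < 0:
        raise ValueError("HCO3 must be nonnegative")
    return (na + math.sqrt(hco3)) / denom * 100.0


def magnesium_hazard(ca: float, mg: float) -> float:
    """MH = Mg / (Ca + Mg) × 100; unsuitable above 50."""
    if ca + mg <= 0:
        raise UndefinedRatioError("Ca + Mg must be positive")
    return mg / (ca + mg) * 100.0


def potential_salinity(cl: float, so4: float) -> float:
    """PS = Cl + 0.5·SO4, meq/L; unsuitable above 3."""
    if cl < 0 or so4 < 0:
        raise ValueError("concentrations must be nonnegative")
    return cl + 0.5 * so4


# ---------------------------------------------------------------------------
# Categorization
# ---------------------------------------------------------------------------

#: index -> ordered (upper bound, label); value <= bound picks the band,
#: the final band has bound None (open above).
CATEGORY_TABLES: dict[str, list[tuple[float | None, str]]] = {
    "na_percent": [(20.0, "excellent"), (40.0, "good"), (60.0, "permissible"),
                   (80.0, "doubtful"), (None, "unsuitable")],
    "sar": [(10.0, "excellent"), (18.0, "good"), (26.0, "doubtful"),
            (None, "unsuitable")],
    # RSC is the one open-below table: good strictly under 1.25
    "rsc": [(1.25, "good"), (2.5, "doubtful"), (None, "unsuitable")],
    "ki": [(1.0, "suitable"), (None, "unsuitable")],
    "mh": [(50.0, "suitable"), (None, "unsuitable")],
    "ps": [(3.0, "suitable"), (None, "unsuitable")],
}


def categorize(index: str, value: float) -> str:
    """Band label for one index value from :data:`CATEGORY_TABLES`.

    PI uses its own three classes: excellent above 75%, suitable 25–75%,
    unsuitable below 25%.
    """
    if index == "pi":
        if value > 75.0:
            return "excellent"
        if value >= 25.0:
            return "suitable"
        return "unsuitable"
    table = CATEGORY_TABLES[index]
    # strict < keeps e.g. RSC 1.25 out of "good"; other tables use closed-left
    strict = index == "rsc"
    for bound, label in table:
        if bound is None:
            return label
        if (value < bound) if strict else (value <= bound):
            return label
    raise AssertionError("unreachable")


def ussl_class(ec: float, sar_value: float) -> str:
    """USSL salinity (C) × sodicity (S) class.

    C1 EC<250, C2 [250,750), C3 [750,2250), C4 ≥2250 µS/cm;
    S1 SAR<10, S2 [10,18), S3 [18,26), S4 ≥26.
    """
    if ec <= 0:
        raise ValueError(f"EC must be positive, got {ec}")
    if sar_value < 0:
        raise ValueError(f"SAR must be nonnegative, got {sar_value}")
    c = "C1" if ec < 250 else "C2" if ec < 750 else "C3" if ec < 2250 else "C4"
    s = "S1" if sar_value < 10 else "S2" if sar_value < 18 else "S3" if sar_value < 26 else "S4"
    return c + s


#: Piecewise-linear Wilcox-diagram zone boundaries in (EC µS/cm, Na%) space.
#: Each boundary is a straight line from (0, na0) to (ec1, 0); a point below
#: or on boundary k (counting from the first) is in zone k. Versioned,
#: overridable approximation of the classic figure.
WILCOX_BOUNDARIES: list[tuple[float, float]] = [
    (60.0, 1250.0),   # excellent-to-good | good-to-permissible
    (75.0, 2000.0),   # good-to-permissible | permissible-to-doubtful
    (90.0, 3000.0),   # permissible-to-doubtful | doubtful-to-unsuitable
    (100.0, 3500.0),  # doubtful-to-unsuitable | unsuitable
]

WILCOX_LABELS = ["excellent-to-good", "good-to-permissible",
                 "permissible-to-doubtful", "doubtful-to-unsuitable",
                 "unsuitable"]


def wilcox_class(ec: float, na_pct: float,
                 boundaries: Sequence[tuple[float, float]] | None = None) -> str:
    """Wilcox EC–Na% class from the documented boundary-line table."""
    if ec <= 0:
        raise ValueError(f"EC must be positive, got {ec}")
    if not 0.0 <= na_pct <= 100.0:
        raise ValueError(f"Na% must be in [0, 100], got {na_pct}")
    boundaries = list(boundaries) if boundaries is not None else WILCOX_BOUNDARIES
    for (na0, ec1), label in zip(boundaries, WILCOX_LABELS):
        bound = na0 * (1.0 - ec / ec1)  # line height at this EC; <0 past x-intercept
        if na_pct <= bound:
            return label
    return WILCOX_LABELS[len(boundaries)]


# ---------------------------------------------------------------------------
# Per-sample assessment
# ---------------------------------------------------------------------------

@dataclass
class IrrigationAssessment:
    site_id: str
    na_percent: float
    sar: float
    rsc: float
    ki: float
    pi: float
    mh: float
    ps: float
    categories: dict[str, str]
    ussl_class: str
    wilcox_class: str


def assess(sample: WaterSample) -> IrrigationAssessment:
    """All seven indices plus diagram classes for one sample (meq/L inside)."""
    na, k = sample.ion_meq("Na"), sample.ion_meq("K")
    ca, mg = sample.ion_meq("Ca"), sample.ion_meq("Mg")
    cl, so4 = sample.ion_meq("Cl"), sample.ion_meq("SO4")
    hco3 = sample.ion_meq("HCO3")
    co3 = sample.ion_meq("CO3") if "CO3" in sample.ions else 0.0

    values = {
        "na_percent": na_percent(na, k, ca, mg),
        "sar": sar(na, ca, mg),
        "rsc": rsc(hco3, co3, ca, mg),
        "ki": kelley_index(na, ca, mg),
        "pi": permeability_index(na, ca, mg, hco3),
        "mh": magnesium_hazard(ca, mg),
        "ps": potential_salinity(cl, so4),
    }
    cats = {idx: categorize(idx, v) for idx, v in values.items()}
    return IrrigationAssessment(
        site_id=sample.site_id,
        **values,
        categories=cats,
        ussl_class=ussl_class(sample.ec, values["sar"]),
        wilcox_class=wilcox_class(sample.ec, values["na_percent"]),
    )


def irrigation_table(samples: Sequence[WaterSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        a = assess(s)
        row = {"site_id": a.site_id, "na_percent": a.na_percent, "sar": a.sar,
               "rsc": a.rsc, "ki": a.ki, "pi": a.pi, "mh": a.mh, "ps": a.ps}
        row.update({f"{k}_category": v for k, v in a.categories.items()})
        row["ussl_class"] = a.ussl_class
        row["wilcox_class"] = a.wilcox_class
        rows.append(row)
    return pd.DataFrame(rows)
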