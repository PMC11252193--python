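"""Hydrochemical facies: Piper trilinear classification, Gibbs dominance
zones, and silicate-weathering molar ratios.

The Piper cation triangle uses Ca / Mg / (Na+K) as percent of the cation
meq sum; the anion triangle uses (HCO3+CO3) / SO4 / Cl of the anion meq
sum (nitrate and fluoride are minor and excluded by convention). The
diamond position is fully determined by the alkali fraction
a = (Na+K)% of cations and the strong-acid fraction b = (Cl+SO4)% of
anions; its six facies fields are encoded as explicit linear inequalities
in (a, b) — see docs/methods.md for the template.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .chemistry import UndefinedRatioError, WaterSample

__all__ = [
    "PiperPoint",
    "GibbsPoint",
    "piper_coordinates",
    "piper_facies",
    "diamond_zone_label",
    "gibbs_zone",
    "weathering_ratios",
    "facies_table",
    "DIAMOND_ZONE_LABELS",
]

DIAMOND_ZONE_LABELS = {
    1: "Ca-HCO3",
    2: "Na-Cl",
    3: "mixed Ca-Na-HCO3",
    4: "mixed Ca-Mg-Cl",
    5: "Ca-Cl",
    6: "Na-HCO3",
}


@dataclass
class PiperPoint:
    site_id: str
    cation_pct: dict[str, float]  # Ca, Mg, NaK; sums to 100
    anion_pct: dict[str, float]  # HCO3CO3, SO4, Cl; sums to 100
    diamond_xy: tuple[float, float]  # (a, b) alkali% × strong-acid%
    cation_zone: str = ""
    anion_zone: str = ""
    diamond_zone: int = 0


@dataclass
class GibbsPoint:
    site_id: str
    tds: float
    na_ratio: float  # Na/(Na+Ca), meq
    cl_ratio: float  # Cl/(Cl+HCO3), meq
    zone_na: str = ""
    zone_cl: str = ""


def piper_coordinates(sample: WaterSample) -> PiperPoint:
    """Ternary percentages and diamond projection for one sample."""
    na, k = sample.ion_meq("Na"), sample.ion_meq("K")
    ca, mg = sample.ion_meq("Ca"), sample.ion_meq("Mg")
    cl, so4 = sample.ion_meq("Cl"), sample.ion_meq("SO4")
    hco3 = sample.ion_meq("HCO3")
    co3 = sample.ion_meq("CO3") if "CO3" in sample.ions else 0.0

    csum = na + k + ca + mg
    asum = cl + so4 + hco3 + co3
    if csum <= 0 or asum <= 0:
        raise UndefinedRatioError(f"{sample.site_id}: zero ionic sum")
    cation_pct = {"Ca": ca / csum * 100, "Mg": mg / csum * 100,
                  "NaK": (na + k) / csum * 100}
    anion_pct = {"HCO3CO3": (hco3 + co3) / asum * 100,
                 "SO4": so4 / asum * 100, "Cl": cl / asum * 100}
    a = cation_pct["NaK"]
    b = anion_pct["SO4"] + anion_pct["Cl"]
    point = PiperPoint(sample.site_id, cation_pct, anion_pct, (a, b))
    return piper_facies(point)


def piper_facies(point: PiperPoint) -> PiperPoint:
    """Assign cation/anion dominance and the diamond facies field.

    Dominance uses the >50% corner rule; otherwise "no-dominant" (the
    central zone of the triangle). Diamond fields in (a, b):
    a+b ≤ 50 → 1 (Ca-HCO3); a+b ≥ 150 → 2 (Na-Cl); b−a ≥ 50 → 5 (Ca-Cl);
    a−b ≥ 50 → 6 (Na-HCO3); remaining central square splits into
    4 (mixed Ca-Mg-Cl, b ≥ a) and 3 (mixed Ca-Na-HCO3, b < a).
    """
    c, an = point.cation_pct, point.anion_pct
    if c["Ca"] > 50:
        point.cation_zone = "calcium-type"
    elif c["Mg"] > 50:
        point.cation_zone = "magnesium-type"
    elif c["NaK"] > 50:
        point.cation_zone = "sodium-type"
    else:
        point.cation_zone = "no-dominant"
    if an["HCO3CO3"] > 50:
        point.anion_zone = "bicarbonate-type"
    elif an["SO4"] > 50:
        point.anion_zone = "sulfate-type"
    elif an["Cl"] > 50:
        point.anion_zone = "chloride-type"
    else:
        point.anion_zone = "no-dominant"

    a, b = point.diamond_xy
    if a + b <= 50:
        point.diamond_zone = 1
    elif a + b >= 150:
        point.diamond_zone = 2
    elif b - a >= 50:
        point.diamond_zone = 5
    elif a - b >= 50:
        point.diamond_zone = 6
    elif b >= a:
        point.diamond_zone = 4
    else:
        point.diamond_zone = 3
    return point


def diamond_zone_label(zone: int) -> str:
    return DIAMOND_ZONE_LABELS[zone]


def gibbs_zone(sample: WaterSample, basis: str = "meq") -> GibbsPoint:
    """Gibbs dominance point: TDS against Na/(Na+Ca) and Cl/(Cl+HCO3).

    Ratios default to meq/L (``basis="mgl"`` for the mass-based variant).
    Zone rule: rock when ratio < 0.5 with TDS in [100, 1000] mg/L;
    evaporation when TDS > 1000 with ratio ≥ 0.5; precipitation when
    TDS < 100 with ratio ≥ 0.5; otherwise outside the envelope.
    """
    if basis == "meq":
        na, ca = sample.ion_meq("Na"), sample.ion_meq("Ca")
        cl, hco3 = sample.ion_meq("Cl"), sample.ion_meq("HCO3")
    elif basis == "mgl":
        na, ca = sample.ion("Na"), sample.ion("Ca")
        cl, hco3 = sample.ion("Cl"), sample.ion("HCO3")
    else:
        raise ValueError(f"basis must be 'meq' or 'mgl', got {basis!r}")
    if na + ca <= 0 or cl + hco3 <= 0:
        raise UndefinedRatioError(f"{sample.site_id}: zero Gibbs denominator")
    na_ratio = na / (na + ca)
    cl_ratio = cl / (cl + hco3)

    def zone(ratio: float) -> str:
        if ratio < 0.5 and 100.0 <= sample.tds <= 1000.0:
            return "rock"
        if sample.tds > 1000.0 and ratio >= 0.5:
            return "evaporation"
        if sample.tds < 100.0 and ratio >= 0.5:
            return "precipitation"
        return "outside"

    return GibbsPoint(sample.site_id, sample.tds, na_ratio, cl_ratio,
                      zone(na_ratio), zone(cl_ratio))


def weathering_ratios(sample: WaterSample) -> dict[str, float]:
    """Molar (mmol/L) source-rock ratios: Ca/Na, Mg/Na, HCO3/Na and
    (Ca+Mg)/(Na+K); the last compares against the ~1.0 crustal-silicate
    reference."""
    na, k = sample.ion_mmol("Na"), sample.ion_mmol("K")
    ca, mg = sample.ion_mmol("Ca"), sample.ion_mmol("Mg")
    hco3 = sample.ion_mmol("HCO3")
    if na <= 0:
        raise UndefinedRatioError(f"{sample.site_id}: Na must be positive for molar ratios")
    if na + k <= 0:
        raise UndefinedRatioError(f"{sample.site_id}: Na+K must be positive")
    return {
        "ca_na": ca / na,
        "mg_na": mg / na,
        "hco3_na": hco3 / na,
        "camg_nak": (ca + mg) / (na + k),
    }


def facies_table(samples: Sequence[WaterSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        p = piper_coordinates(s)
        g = gibbs_zone(s)
        w = weathering_ratios(s)
        rows.append({
            "site_id": s.site_id,
            "cation_Ca_pct": p.cation_pct["Ca"],
            "cation_Mg_pct": p.cation_pct["Mg"],
            "cation_NaK_pct": p.cation_pct["NaK"],
            "anion_HCO3CO3_pct": p.anion_pct["HCO3CO3"],
            "anion_SO4_pct": p.anion_pct["SO4"],
            "anion_Cl_pct": p.anion_pct["Cl"],
            "diamond_a": p.diamond_xy[0],
            "diamond_b": p.diamond_xy[1],
            "cation_zone": p.cation_zone,
            "anion_zone": p.anion_zone,
            "diamond_zone": p.diamond_zone,
            "diamond_facies": diamond_zone_label(p.diamond_zone),
            "gibbs_na_ratio": g.na_ratio,
            "gibbs_cl_ratio": g.cl_ratio,
            "gibbs_zone_na": g.zone_na,
            "gibbs_zone_cl": g.zone_cl,
            **{f"ratio_{k}": v for k, v in w.items()},
        })
    return pd.DataFrame(rows)
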