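"""Deterministic non-carcinogenic human health risk for nitrate and fluoride.

Exposure chain per chemical and subpopulation:

    ADI_ing  = Cw · IR_ing · EF · ED / (BW · AT)
    ADI_derm = Cw · Sa · Kp · T · EV · EF · ED · CF / (BW · AT)
    HQ_ing   = ADI_ing / RfDo
    HQ_derm  = ADI_derm / (RfDo · GIABS)
    THQ      = HQ_ing + HQ_derm        (per chemical)
    HI       = Σ_chemicals THQ

with concern flagged at HI > 1 (strict). Default parameter sets for
children, adult females and adult males are shipped and fully
overridable through JSON config; see docs/methods.md for the values,
units and rationale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .chemistry import WaterSample

__all__ = [
    "ExposureParameters",
    "ToxicityReference",
    "ChemicalRisk",
    "RiskResult",
    "DEFAULT_EXPOSURE",
    "DEFAULT_TOXICITY",
    "adi_ingestion",
    "adi_dermal",
    "hazard_quotients",
    "hazard_index",
    "assess_sample",
    "assess_cohort",
    "risk_summary",
    "risk_table",
    "load_exposure_config",
]


class ParameterError(ValueError):
    """Invalid exposure or toxicity parameter."""


@dataclass(frozen=True)
class ExposureParameters:
    """One subpopulation's exposure constants.

    Units: IR_ing L/day; EF days/year; ED years; BW kg; AT days;
    Sa cm²; Kp cm/hour; T hours/event; EV events/day; CF L/cm³.
    """

    subpopulation: str
    IR_ing: float
    EF: float
    ED: float
    BW: float
    Sa: float
    Kp: float
    T: float
    EV: float
    CF: float = 0.001
    AT: float | None = None  # defaults to ED × 365 (non-carcinogenic)

    def __post_init__(self) -> None:
        at = self.AT if self.AT is not None else self.ED * 365.0
        object.__setattr__(self, "AT", at)
        for name in ("IR_ing", "EF", "ED", "BW", "AT", "Sa", "Kp", "T", "EV", "CF"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{self.subpopulation}: {name} must be positive")


@dataclass(frozen=True)
class ToxicityReference:
    chemical: str
    RfDo: float  # mg/kg/day
    GIABS: float = 1.0

    def __post_init__(self) -> None:
        if self.RfDo <= 0:
            raise ParameterError(f"{self.chemical}: RfDo must be positive")
        if not 0.0 < self.GIABS <= 1.0:
            raise ParameterError(f"{self.chemical}: GIABS must be in (0, 1]")


DEFAULT_EXPOSURE: dict[str, ExposureParameters] = {
    "children": ExposureParameters("children", IR_ing=1.0, EF=365, ED=6,
                                   BW=15, Sa=6600, Kp=0.001, T=0.4, EV=1),
    "adult_female": ExposureParameters("adult_female", IR_ing=2.5, EF=365, ED=30,
                                       BW=55, Sa=16600, Kp=0.001, T=0.4, EV=1),
    "adult_male": ExposureParameters("adult_male", IR_ing=2.5, EF=365, ED=30,
                                     BW=65, Sa=18000, Kp=0.001, T=0.4, EV=1),
}

DEFAULT_TOXICITY: dict[str, ToxicityReference] = {
    "NO3": ToxicityReference("NO3", RfDo=1.6),
    "F": ToxicityReference("F", RfDo=0.06),
}


def adi_ingestion(cw: float, p: ExposureParameters) -> float:
    """Average daily intake by drinking, mg/kg/day."""
    if cw < 0:
        raise ValueError(f"concentration must be nonnegative, got {cw}")
    return cw * p.IR_ing * p.EF * p.ED / (p.BW * p.AT)


def adi_dermal(cw: float, p: ExposureParameters) -> float:
    """Average daily intake through skin contact, mg/kg/day; CF converts
    the Sa·Kp·T volume from cm³ to L."""
    if cw < 0:
        raise ValueError(f"concentration must be nonnegative, got {cw}")
    return cw * p.Sa * p.Kp * p.T * p.EV * p.EF * p.ED * p.CF / (p.BW * p.AT)


def hazard_quotients(adi_ing: float, adi_derm: float,
                     tox: ToxicityReference) -> tuple[float, float]:
    """(HQ_ing, HQ_derm) = ADI/RfDo and ADI/(RfDo·GIABS)."""
    return adi_ing / tox.RfDo, adi_derm / (tox.RfDo * tox.GIABS)


@dataclass
class ChemicalRisk:
    chemical: str
    adi_ing: float
    adi_derm: float
    hq_ing: float
    hq_derm: float

    @property
    def thq(self) -> float:
        return self.hq_ing + self.hq_derm


@dataclass
class RiskResult:
    site_id: str
    subpopulation: str
    chemicals: dict[str, ChemicalRisk] = field(default_factory=dict)

    @property
    def hi(self) -> float:
        return sum(c.thq for c in self.chemicals.values())

    @property
    def flagged(self) -> bool:
        return self.hi > 1.0


def hazard_index(thqs: Mapping[str, float]) -> float:
    """HI = Σ per-chemical THQ."""
    if not thqs:
        raise ValueError("need at least one chemical THQ")
    return float(sum(thqs.values()))


def assess_sample(sample: WaterSample,
                  exposure: Mapping[str, ExposureParameters] | None = None,
                  toxicity: Mapping[str, ToxicityReference] | None = None,
                  ) -> list[RiskResult]:
    """Full risk chain for one sample, one RiskResult per subpopulation."""
    exposure = exposure or DEFAULT_EXPOSURE
    toxicity = toxicity or DEFAULT_TOXICITY
    results = []
    for pop, p in exposure.items():
        res = RiskResult(sample.site_id, pop)
        for chem, tox in toxicity.items():
            cw = sample.ion(chem)
            ai = adi_ingestion(cw, p)
            ad = adi_dermal(cw, p)
            hq_i, hq_d = hazard_quotients(ai, ad, tox)
            res.chemicals[chem] = ChemicalRisk(chem, ai, ad, hq_i, hq_d)
        results.append(res)
    return results


def assess_cohort(samples: Sequence[WaterSample],
                  exposure: Mapping[str, ExposureParameters] | None = None,
                  toxicity: Mapping[str, ToxicityReference] | None = None,
                  ) -> list[RiskResult]:
    out: list[RiskResult] = []
    for s in samples:
        out.extend(assess_sample(s, exposure, toxicity))
    return out


def risk_summary(results: Sequence[RiskResult], threshold: float = 1.0) -> pd.DataFrame:
    """Per-subpopulation fractions of sites with any HQ_ing, any THQ, and
    HI above ``threshold`` (strict)."""
    if not results:
        raise ValueError("no risk results")
    rows = []
    pops = sorted({r.subpopulation for r in results})
    for pop in pops:
        group = [r for r in results if r.subpopulation == pop]
        n = len(group)
        frac_hq = sum(any(c.hq_ing > threshold for c in r.chemicals.values())
                      for r in group) / n
        frac_thq = sum(any(c.thq > threshold for c in r.chemicals.values())
                       for r in group) / n
        frac_hi = sum(r.hi > threshold for r in group) / n
        rows.append({"subpopulation": pop, "n": n,
                     "frac_hq_ing_above": frac_hq,
                     "frac_thq_above": frac_thq,
                     "frac_hi_above": frac_hi,
                     "mean_hi": sum(r.hi for r in group) / n})
    return pd.DataFrame(rows)


def risk_table(results: Sequence[RiskResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row: dict = {"site_id": r.site_id, "subpopulation": r.subpopulation}
        for chem, c in r.chemicals.items():
            row.update({f"adi_ing_{chem}": c.adi_ing, f"adi_derm_{chem}": c.adi_derm,
                        f"hq_ing_{chem}": c.hq_ing, f"hq_derm_{chem}": c.hq_derm,
                        f"thq_{chem}": c.thq})
        row["hi"] = r.hi
        row["flagged"] = r.flagged
        rows.append(row)
    return pd.DataFrame(rows)


def load_exposure_config(path: str | Path) -> tuple[dict[str, ExposureParameters],
                                                    dict[str, ToxicityReference]]:
    """Read {"subpopulations": {...}, "toxicity": {...}} JSON overrides."""
    raw = json.loads(Path(path).read_text())
    expo = {
        name: ExposureParameters(subpopulation=name, **spec)
        for name, spec in raw.get("subpopulations", {}).items()
    }
    tox = {
        chem: ToxicityReference(chemical=chem, **spec)
        for chem, spec in raw.get("toxicity", {}).items()
    }
    return expo or dict(DEFAULT_EXPOSURE), tox or dict(DEFAULT_TOXICITY)
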