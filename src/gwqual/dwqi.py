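"""Weighted-arithmetic drinking-water quality index (DWQI).

Each parameter gets an assigned health-impact weight wi; the relative
weight is Wi = wi / Σwi, the quality rating qi = 100·Ci/Si against the
guideline limit Si, the subindex SIi = Wi·qi, and the index is WQI = ΣSIi.
A water at exactly the guideline composition therefore scores 100.

The default registry carries the WHO-limit scheme over the thirteen
weighted parameters (pH, EC, TDS, Na, K, Mg, Ca, F, Cl, SO4, HCO3, NO3,
turbidity); carbonate and hardness are measured but carry no weight and
are excluded from the index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .chemistry import WaterSample

__all__ = [
    "GuidelineEntry",
    "GuidelineRegistry",
    "WQIResult",
    "DEFAULT_REGISTRY",
    "relative_weights",
    "quality_rating",
    "compute_wqi",
    "classify_wqi",
    "wqi_table",
]

#: Category bands, half-open on the left band's upper edge.
CATEGORY_BOUNDS = [
    (25.0, "excellent"),
    (50.0, "good"),
    (75.0, "poor"),
    (100.0, "very poor"),
]


class ConfigurationError(ValueError):
    """Invalid guideline registry or weights."""


@dataclass(frozen=True)
class GuidelineEntry:
    si: float  # standard limit, parameter units (upper bound for pH)
    wi: float | None = None  # assigned weight; None = not in the index
    source: str = "WHO"
    lower: float | None = None  # lower bound, only for interval limits (pH)

    def __post_init__(self) -> None:
        if self.si <= 0:
            raise ConfigurationError(f"Si must be positive, got {self.si}")
        if self.wi is not None and self.wi <= 0:
            raise ConfigurationError(f"wi must be positive, got {self.wi}")


@dataclass
class GuidelineRegistry:
    """Per-parameter guideline limit Si and assigned weight wi."""

    entries: dict[str, GuidelineEntry] = field(default_factory=dict)

    def weighted(self) -> dict[str, GuidelineEntry]:
        return {p: e for p, e in self.entries.items() if e.wi is not None}

    @classmethod
    def from_json(cls, path: str | Path) -> "GuidelineRegistry":
        raw = json.loads(Path(path).read_text())
        entries = {}
        for param, spec in raw.items():
            entries[param] = GuidelineEntry(
                si=float(spec["si"]),
                wi=float(spec["wi"]) if spec.get("wi") is not None else None,
                source=spec.get("source", "custom"),
                lower=float(spec["lower"]) if spec.get("lower") is not None else None,
            )
        return cls(entries)

    def to_json(self, path: str | Path) -> None:
        out = {
            p: {"si": e.si, "wi": e.wi, "source": e.source,
                **({"lower": e.lower} if e.lower is not None else {})}
            for p, e in self.entries.items()
        }
        Path(path).write_text(json.dumps(out, indent=1))


def _default_registry() -> GuidelineRegistry:
    # WHO-limit scheme; pH rated against the interval's upper edge 8.5.
    spec = {
        "pH": (8.5, 3.7, 6.5),
        "EC": (1000.0, 3.2, None),
        "TDS": (1000.0, 4.3, None),
        "Na": (200.0, 2.9, None),
        "K": (12.0, 2.0, None),
        "Mg": (50.0, 2.3, None),
        "Ca": (75.0, 2.4, None),
        "F": (1.5, 5.0, None),
        "Cl": (250.0, 3.5, None),
        "SO4": (250.0, 3.9, None),
        "HCO3": (500.0, 2.2, None),
        "NO3": (45.0, 4.9, None),
        "Turbidity": (5.0, 2.5, None),
        # measured but unweighted:
        "CO3": (10.0, None, None),
        "Hardness": (500.0, None, None),
    }
    return GuidelineRegistry({
        p: GuidelineEntry(si=si, wi=wi, lower=lo) for p, (si, wi, lo) in spec.items()
    })


DEFAULT_REGISTRY = _default_registry()


@dataclass
class WQIResult:
    site_id: str
    qi: dict[str, float]  # quality rating, % of standard
    subindex: dict[str, float]  # Wi × qi
    wqi: float
    category: str


def relative_weights(registry: GuidelineRegistry) -> dict[str, float]:
    """Wi = wi / Σwi over the weighted parameters; the Wi sum to 1."""
    weighted = registry.weighted()
    if not weighted:
        raise ConfigurationError("registry has no weighted parameters")
    total = sum(e.wi for e in weighted.values())
    return {p: e.wi / total for p, e in weighted.items()}


def quality_rating(ci: float, si: float) -> float:
    """qi = 100 · Ci / Si (percent of the guideline; unbounded above)."""
    if si <= 0:
        raise ConfigurationError(f"Si must be positive, got {si}")
    if ci < 0:
        raise ValueError(f"concentration must be nonnegative, got {ci}")
    return 100.0 * ci / si


def classify_wqi(wqi: float) -> str:
    """Map a WQI value to its drinking-suitability band.

    [0, 25] excellent, (25, 50] good, (50, 75] poor, (75, 100] very poor,
    > 100 undrinkable.
    """
    if wqi < 0:
        raise ValueError(f"WQI must be nonnegative, got {wqi}")
    for upper, label in CATEGORY_BOUNDS:
        if wqi <= upper:
            return label
    return "undrinkable"


def compute_wqi(sample: WaterSample, registry: GuidelineRegistry | None = None) -> WQIResult:
    """Full index for one sample; raises listing every missing parameter."""
    registry = registry or DEFAULT_REGISTRY
    weights = relative_weights(registry)
    missing = []
    qi: dict[str, float] = {}
    for param in weights:
        try:
            ci = sample.value(param)
        except KeyError:
            missing.append(param)
            continue
        qi[param] = quality_rating(ci, registry.entries[param].si)
    if missing:
        raise KeyError(f"{sample.site_id}: missing WQI parameter(s): {', '.join(missing)}")
    subindex = {p: weights[p] * qi[p] for p in qi}
    wqi = sum(subindex.values())
    return WQIResult(sample.site_id, qi, subindex, wqi, classify_wqi(wqi))


def wqi_table(samples: Sequence[WaterSample],
              registry: GuidelineRegistry | None = None) -> pd.DataFrame:
    """Per-site WQI results as a tidy frame (one qi_<param> column each)."""
    rows = []
    for s in samples:
        res = compute_wqi(s, registry)
        row: dict = {"site_id": res.site_id, "wqi": res.wqi, "category": res.category}
        row.update({f"qi_{p}": v for p, v in res.qi.items()})
        rows.append(row)
    return pd.DataFrame(rows)
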