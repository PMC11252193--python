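"""Core data model for per-well groundwater chemistry.

Holds the :class:`WaterSample` record consumed by every downstream stage,
the major-ion registry with equivalent weights, strict CSV ingestion,
mg/L <-> meq/L <-> mmol/L conversion, and charge-balance quality control.

All concentrations are stored in mg/L; the meq-based indices downstream
convert through :func:`to_meq` so there is a single conversion path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IonMeta",
    "WaterSample",
    "QCReport",
    "ION_REGISTRY",
    "CATIONS",
    "ANIONS",
    "DEFAULT_COLUMNS",
    "load_samples",
    "samples_to_frame",
    "to_meq",
    "to_mgl",
    "to_mmol",
    "charge_balance_error",
    "exceedance_table",
]


class SchemaError(ValueError):
    """Input table does not match the expected column schema."""


class RegistryError(KeyError):
    """Ion or parameter not present in the relevant registry."""


class UndefinedRatioError(ZeroDivisionError):
    """A ratio whose denominator is identically zero."""


@dataclass(frozen=True)
class IonMeta:
    """Chemical metadata for one major ion.

    ``equivalent_weight`` (g/eq, the divisor taking mg/L to meq/L) defaults
    to molar mass / |charge| but can be pinned to the conventional rounded
    value used throughout the water-chemistry literature (e.g. Mg 12.15,
    CO3 30.00).
    """

    name: str
    charge: int
    molar_mass: float  # g/mol
    role: str  # "cation" | "anion"
    equivalent_weight: float | None = None  # g/eq

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError(f"{self.name}: ion charge cannot be zero")
        expected = "cation" if self.charge > 0 else "anion"
        if self.role != expected:
            raise ValueError(f"{self.name}: role {self.role!r} inconsistent with charge {self.charge}")
        if self.equivalent_weight is None:
            object.__setattr__(self, "equivalent_weight",
                               self.molar_mass / abs(self.charge))
        if self.equivalent_weight <= 0:
            raise ValueError(f"{self.name}: equivalent weight must be positive")


# IUPAC molar masses with the conventional rounded equivalent weights
# (Ca 20.04, Mg 12.15, Na 22.99, K 39.10, Cl 35.45, SO4 48.03, HCO3 61.02,
#  CO3 30.00, NO3 62.00, F 19.00).
ION_REGISTRY: dict[str, IonMeta] = {
    "Na": IonMeta("Na", +1, 22.99, "cation", 22.99),
    "K": IonMeta("K", +1, 39.10, "cation", 39.10),
    "Ca": IonMeta("Ca", +2, 40.08, "cation", 20.04),
    "Mg": IonMeta("Mg", +2, 24.305, "cation", 12.15),
    "Cl": IonMeta("Cl", -1, 35.45, "anion", 35.45),
    "SO4": IonMeta("SO4", -2, 96.06, "anion", 48.03),
    "HCO3": IonMeta("HCO3", -1, 61.02, "anion", 61.02),
    "CO3": IonMeta("CO3", -2, 60.01, "anion", 30.00),
    "NO3": IonMeta("NO3", -1, 62.00, "anion", 62.00),
    "F": IonMeta("F", -1, 19.00, "anion", 19.00),
}

CATIONS: tuple[str, ...] = ("Na", "K", "Ca", "Mg")
ANIONS: tuple[str, ...] = ("Cl", "SO4", "HCO3", "CO3", "NO3", "F")


@dataclass
class WaterSample:
    """One site's physicochemical record.

    ``ions`` maps ion name to concentration in mg/L; a missing ion is an
    explicit absence, never a silent zero, so stages requiring it fail
    loudly per sample.
    """

    site_id: str
    ph: float
    ec: float  # µS/cm
    tds: float  # mg/L
    turbidity: float  # NTU
    hardness: float  # mg/L as CaCO3
    ions: dict[str, float] = field(default_factory=dict)
    lon: float | None = None
    lat: float | None = None
    color_ok: bool | None = None
    odor_ok: bool | None = None
    taste_ok: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError(f"{self.site_id}: pH {self.ph} outside [0, 14]")
        for name, conc in self.ions.items():
            if name not in ION_REGISTRY:
                raise RegistryError(f"{self.site_id}: unknown ion {name!r}")
            if conc < 0:
                raise ValueError(f"{self.site_id}: negative {name} concentration {conc}")
        for attr in ("ec", "tds", "turbidity", "hardness"):
            v = getattr(self, attr)
            if v is not None and v < 0:
                raise ValueError(f"{self.site_id}: negative {attr} {v}")

    def ion(self, name: str) -> float:
        """Concentration of ``name`` in mg/L; raises if absent."""
        if name not in self.ions:
            raise RegistryError(f"{self.site_id}: ion {name!r} not measured")
        return self.ions[name]

    def ion_meq(self, name: str) -> float:
        return to_meq(self.ion(name), ION_REGISTRY[name])

    def ion_mmol(self, name: str) -> float:
        return to_mmol(self.ion(name), ION_REGISTRY[name])

    def value(self, parameter: str) -> float:
        """Look up any WQI-style parameter (field name or ion) in native units."""
        aliases = {"pH": "ph", "EC": "ec", "TDS": "tds",
                   "Turbidity": "turbidity", "Hardness": "hardness"}
        if parameter in aliases:
            return getattr(self, aliases[parameter])
        return self.ion(parameter)


@dataclass
class QCReport:
    site_id: str
    sum_cations: float  # meq/L
    sum_anions: float  # meq/L
    cbe_percent: float
    passed: bool


DEFAULT_COLUMNS: dict[str, str] = {
    "site_id": "site_id",
    "lon": "lon",
    "lat": "lat",
    "ph": "pH",
    "ec": "EC_uScm",
    "tds": "TDS_mgL",
    "turbidity": "Turbidity_NTU",
    "hardness": "Hardness_mgL",
    "Na": "Na_mgL",
    "K": "K_mgL",
    "Ca": "Ca_mgL",
    "Mg": "Mg_mgL",
    "Cl": "Cl_mgL",
    "SO4": "SO4_mgL",
    "HCO3": "HCO3_mgL",
    "CO3": "CO3_mgL",
    "NO3": "NO3_mgL",
    "F": "F_mgL",
}

_MANDATORY = ("site_id", "ph", "ec", "tds", "turbidity", "hardness") + CATIONS + ANIONS
_OPTIONAL = ("lon", "lat")


def load_samples(path: str | Path, schema: Mapping[str, str] | None = None) -> list[WaterSample]:
    """Read a per-site CSV into :class:`WaterSample` records, row order preserved.

    ``schema`` maps logical field names (keys of :data:`DEFAULT_COLUMNS`) to
    the file's column headers. Numeric parsing is strict: a non-numeric cell
    raises with the offending row index rather than coercing to NaN.
    """
    schema = dict(DEFAULT_COLUMNS, **(schema or {}))
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)

    missing = [schema[k] for k in _MANDATORY if schema[k] not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    def parse(row_idx: int, col: str, raw: str) -> float | None:
        raw = raw.strip()
        if raw == "":
            return None
        try:
            return float(raw)
        except ValueError:
            raise SchemaError(
                f"non-numeric value {raw!r} in column {col!r} at data row {row_idx}"
            ) from None

    samples: list[WaterSample] = []
    for idx, row in df.iterrows():
        kwargs: dict = {"site_id": str(row[schema["site_id"]])}
        for fld in ("ph", "ec", "tds", "turbidity", "hardness"):
            v = parse(idx, schema[fld], row[schema[fld]])
            if v is None:
                raise SchemaError(f"empty mandatory cell {schema[fld]!r} at data row {idx}")
            kwargs[fld] = v
        ions: dict[str, float] = {}
        for ion in CATIONS + ANIONS:
            v = parse(idx, schema[ion], row[schema[ion]])
            if v is not None:
                ions[ion] = v
        kwargs["ions"] = ions
        for fld in _OPTIONAL:
            col = schema[fld]
            if col in df.columns:
                kwargs[fld] = parse(idx, col, row[col])
        samples.append(WaterSample(**kwargs))
    return samples


def samples_to_frame(samples: Sequence[WaterSample]) -> pd.DataFrame:
    """Flatten samples into a DataFrame with the default column names."""
    rows = []
    for s in samples:
        row = {"site_id": s.site_id, "lon": s.lon, "lat": s.lat,
               "pH": s.ph, "EC_uScm": s.ec, "TDS_mgL": s.tds,
               "Turbidity_NTU": s.turbidity, "Hardness_mgL": s.hardness}
        for ion in CATIONS + ANIONS:
            row[f"{ion}_mgL"] = s.ions.get(ion)
        rows.append(row)
    return pd.DataFrame(rows)


def to_meq(concentration: float, ion: IonMeta | str) -> float:
    """mg/L -> meq/L: divide by the equivalent weight (molar mass / |charge|)."""
    if isinstance(ion, str):
        if ion not in ION_REGISTRY:
            raise RegistryError(f"unknown ion {ion!r}")
        ion = ION_REGISTRY[ion]
    if concentration < 0:
        raise ValueError(f"negative concentration {concentration}")
    return concentration / ion.equivalent_weight


def to_mgl(meq: float, ion: IonMeta | str) -> float:
    """Inverse of :func:`to_meq`."""
    if isinstance(ion, str):
        if ion not in ION_REGISTRY:
            raise RegistryError(f"unknown ion {ion!r}")
        ion = ION_REGISTRY[ion]
    return meq * ion.equivalent_weight


def to_mmol(concentration: float, ion: IonMeta | str) -> float:
    """mg/L -> mmol/L: divide by the molar mass."""
    if isinstance(ion, str):
        if ion not in ION_REGISTRY:
            raise RegistryError(f"unknown ion {ion!r}")
        ion = ION_REGISTRY[ion]
    if concentration < 0:
        raise ValueError(f"negative concentration {concentration}")
    return concentration / ion.molar_mass


def charge_balance_error(sample: WaterSample, threshold: float = 10.0) -> QCReport:
    """Charge-balance error %CBE = (Σcat − Σan) / (Σcat + Σan) × 100 in meq/L.

    Cations {Na, K, Ca, Mg} against anions {Cl, SO4, HCO3, CO3, NO3, F};
    an analysis passes QC when |%CBE| is within ``threshold`` (±10 by default).
    Missing ions count as absent: at least one cation and one anion must be
    measured, and an all-zero ion vector is an error rather than NaN.
    """
    cats = [ion for ion in CATIONS if ion in sample.ions]
    ans = [ion for ion in ANIONS if ion in sample.ions]
    if not cats or not ans:
        raise RegistryError(f"{sample.site_id}: need at least one measured cation and anion")
    sum_cat = sum(sample.ion_meq(i) for i in cats)
    sum_an = sum(sample.ion_meq(i) for i in ans)
    if sum_cat + sum_an == 0:
        raise UndefinedRatioError(f"{sample.site_id}: all measured ions are zero")
    cbe = (sum_cat - sum_an) / (sum_cat + sum_an) * 100.0
    return QCReport(sample.site_id, sum_cat, sum_an, cbe, abs(cbe) <= threshold)


def exceedance_table(samples: Sequence[WaterSample], registry) -> pd.Series:
    """Fraction of samples exceeding each guideline limit.

    ``registry`` is a :class:`gwqual.dwqi.GuidelineRegistry`. pH is counted
    as exceeding when outside its [lower, upper] interval; everything else
    exceeds when strictly above Si. Parameters without a limit are skipped
    (logged), mirroring survey practice.
    """
    out: dict[str, float] = {}
    n = len(samples)
    if n == 0:
        raise ValueError("no samples")
    for param, entry in registry.entries.items():
        try:
            values = [s.value(param) for s in samples]
        except RegistryError:
            logger.info("exceedance: parameter %r not measured in all samples, skipped", param)
            continue
        if param == "pH" and entry.lower is not None:
            count = sum(1 for v in values if not (entry.lower <= v <= entry.si))
        else:
            count = sum(1 for v in values if v > entry.si)
        out[param] = count / n
    return pd.Series(out, name="fraction_exceeding")
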