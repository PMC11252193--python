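"""End-to-end assessment runner.

Binds the stages — load → ionic QC → drinking-water index → irrigation
indices → facies → health risk → descriptive statistics → optional
surface maps — writes every per-sample table as CSV, and produces a
summary report (JSON + Markdown) with category percentages and a
provenance block. Stage errors are isolated per sample (an error column)
rather than aborting the cohort.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .chemistry import WaterSample, charge_balance_error, exceedance_table, load_samples
from .dwqi import DEFAULT_REGISTRY, GuidelineRegistry, wqi_table
from .facies import facies_table
from .hhra import (DEFAULT_EXPOSURE, DEFAULT_TOXICITY, assess_cohort,
                   load_exposure_config, risk_summary, risk_table)
from .irrigation import irrigation_table
from .stats import correlation_pairs, describe, pearson_matrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SummaryReport", "run", "category_percentages"]

ALL_STAGES = ("qc", "wqi", "irrigation", "facies", "hhra", "stats", "maps")


@dataclass
class RunConfig:
    input_path: str | Path
    output_dir: str | Path
    registry_path: str | Path | None = None
    exposure_path: str | Path | None = None
    stages: tuple[str, ...] = ("qc", "wqi", "irrigation", "facies", "hhra", "stats")
    seed: int = 0
    cbe_threshold: float = 10.0

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")


@dataclass
class SummaryReport:
    n_samples: int
    qc_pass_rate: float | None = None
    category_counts: dict[str, dict[str, float]] = field(default_factory=dict)
    tables: dict[str, str] = field(default_factory=dict)  # stage -> written file
    errors: dict[str, list[str]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, default=str)

    def to_markdown(self) -> str:
        lines = ["# Groundwater assessment summary", "",
                 f"Samples: {self.n_samples}"]
        if self.qc_pass_rate is not None:
            lines.append(f"QC pass rate: {100 * self.qc_pass_rate:.2f}%")
        for name, split in self.category_counts.items():
            lines.append(f"\n## {name}")
            for label, pct in split.items():
                lines.append(f"- {label}: {pct:.2f}%")
        if self.errors:
            lines.append("\n## Per-sample errors")
            for stage, errs in self.errors.items():
                for e in errs:
                    lines.append(f"- {stage}: {e}")
        lines.append("\n## Provenance")
        for k, v in self.provenance.items():
            lines.append(f"- {k}: {v}")
        return "\n".join(lines) + "\n"


def category_percentages(labels: Sequence[str]) -> dict[str, float]:
    """Percent of samples per label, 2 dp, summing to 100 ± rounding."""
    if not labels:
        raise ValueError("no labels")
    counts = Counter(labels)
    n = len(labels)
    return {label: round(100.0 * c / n, 2) for label, c in sorted(counts.items())}


def _config_hash(config: RunConfig) -> str:
    parts = [str(config.input_path), str(config.registry_path),
             str(config.exposure_path), ",".join(config.stages),
             str(config.seed), str(config.cbe_threshold)]
    return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]


def run(config: RunConfig) -> SummaryReport:
    """Execute the enabled stages; returns the summary (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = load_samples(config.input_path)
    registry = (GuidelineRegistry.from_json(config.registry_path)
                if config.registry_path else DEFAULT_REGISTRY)
    if config.exposure_path:
        exposure, toxicity = load_exposure_config(config.exposure_path)
    else:
        exposure, toxicity = DEFAULT_EXPOSURE, DEFAULT_TOXICITY

    report = SummaryReport(n_samples=len(samples))
    report.provenance = {
        "gwqual_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "input": str(config.input_path),
    }

    def _stage_tables(stage: str, fn, per_sample: bool):
        """Run fn per sample (or on the cohort), isolating failures."""
        errors: list[str] = []
        if per_sample:
            frames = []
            for s in samples:
                try:
                    frames.append(fn([s]))
                except Exception as exc:  # noqa: BLE001 - per-sample isolation
                    errors.append(f"{s.site_id}: {exc}")
            table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        else:
            table = fn(samples)
        if errors:
            report.errors[stage] = errors
        return table

    if "qc" in config.stages:
        rows, errors = [], []
        for s in samples:
            try:
                q = charge_balance_error(s, config.cbe_threshold)
                rows.append({"site_id": q.site_id, "sum_cations_meqL": q.sum_cations,
                             "sum_anions_meqL": q.sum_anions,
                             "cbe_percent": q.cbe_percent, "pass": q.passed})
            except Exception as exc:  # noqa: BLE001
                errors.append(f"{s.site_id}: {exc}")
        qc = pd.DataFrame(rows)
        if errors:
            report.errors["qc"] = errors
        if len(qc):
            report.qc_pass_rate = float(qc["pass"].mean())
        path = outdir / "qc.csv"
        qc.to_csv(path, index=False)
        report.tables["qc"] = str(path)
        try:
            exc_table = exceedance_table(samples, registry)
            exc_path = outdir / "exceedance.csv"
            exc_table.to_csv(exc_path, header=True)
            report.tables["exceedance"] = str(exc_path)
        except Exception as exc:  # noqa: BLE001
            report.errors.setdefault("qc", []).append(f"exceedance: {exc}")

    if "wqi" in config.stages:
        table = _stage_tables("wqi", lambda ss: wqi_table(ss, registry), True)
        path = outdir / "wqi.csv"
        table.to_csv(path, index=False)
        report.tables["wqi"] = str(path)
        if len(table):
            report.category_counts["drinking_water_quality"] = (
                category_percentages(list(table["category"])))

    if "irrigation" in config.stages:
        table = _stage_tables("irrigation", irrigation_table, True)
        path = outdir / "irrigation.csv"
        table.to_csv(path, index=False)
        report.tables["irrigation"] = str(path)
        if len(table):
            for idx in ("na_percent", "sar", "rsc", "ki", "pi", "mh", "ps"):
                report.category_counts[f"irrigation_{idx}"] = (
                    category_percentages(list(table[f"{idx}_category"])))
            report.category_counts["ussl"] = category_percentages(list(table["ussl_class"]))
            report.category_counts["wilcox"] = category_percentages(list(table["wilcox_class"]))

    if "facies" in config.stages:
        table = _stage_tables("facies", facies_table, True)
        path = outdir / "facies.csv"
        table.to_csv(path, index=False)
        report.tables["facies"] = str(path)
        if len(table):
            report.category_counts["piper_diamond"] = (
                category_percentages([str(z) for z in table["diamond_facies"]]))
            report.category_counts["gibbs_na"] = (
                category_percentages(list(table["gibbs_zone_na"])))

    if "hhra" in config.stages:
        try:
            results = assess_cohort(samples, exposure, toxicity)
            table = risk_table(results)
            path = outdir / "hhra.csv"
            table.to_csv(path, index=False)
            report.tables["hhra"] = str(path)
            summary = risk_summary(results)
            spath = outdir / "hhra_summary.csv"
            summary.to_csv(spath, index=False)
            report.tables["hhra_summary"] = str(spath)
            for _, row in summary.iterrows():
                report.category_counts[f"risk_{row['subpopulation']}"] = {
                    "hi_above_1_pct": round(100 * row["frac_hi_above"], 2),
                    "hi_below_1_pct": round(100 * (1 - row["frac_hi_above"]), 2),
                }
        except Exception as exc:  # noqa: BLE001
            report.errors["hhra"] = [str(exc)]

    if "stats" in config.stages:
        from .chemistry import samples_to_frame

        df = samples_to_frame(samples)
        try:
            desc = describe(df)
            path = outdir / "descriptive.csv"
            desc.to_csv(path, index=False)
            report.tables["descriptive"] = str(path)
            cm = pearson_matrix(df)
            cm.r.to_csv(outdir / "correlation_r.csv")
            correlation_pairs(cm).to_csv(outdir / "correlation_pairs.csv", index=False)
            report.tables["correlation"] = str(outdir / "correlation_r.csv")
        except Exception as exc:  # noqa: BLE001
            report.errors["stats"] = [str(exc)]

    if "maps" in config.stages:
        try:
            report.tables.update(_run_maps(samples, outdir))
        except Exception as exc:  # noqa: BLE001
            report.errors["maps"] = [str(exc)]

    (outdir / "report.json").write_text(report.to_json())
    (outdir / "report.md").write_text(report.to_markdown())
    return report


def _run_maps(samples: Sequence[WaterSample], outdir: Path,
              parameters: tuple[str, ...] = ("TDS", "F", "NO3"),
              interpolator: str = "kriging") -> dict[str, str]:
    """Interpolate selected parameters onto a grid; CSV (x, y, value) out."""
    import numpy as np

    from .spatial import (empirical_variogram, fit_variogram, idw, krige,
                          make_grid, project_local)

    located = [s for s in samples if s.lon is not None and s.lat is not None]
    if len(located) < 10:
        raise ValueError("need >= 10 located samples for mapping")
    pts = project_local(np.array([s.lon for s in located]),
                        np.array([s.lat for s in located]))
    span = float(max(pts.max(0) - pts.min(0)))
    grid = make_grid(pts, cell_size=span / 40.0)
    written: dict[str, str] = {}
    for param in parameters:
        vals = np.array([s.value(param) for s in located])
        if interpolator == "kriging":
            model = fit_variogram(empirical_variogram(pts, vals))
            surf = krige(pts, vals, model, grid)
        else:
            surf = idw(pts, vals, grid)
        path = outdir / f"map_{param}.csv"
        surf.to_table().to_csv(path, index=False)
        written[f"map_{param}"] = str(path)
    return written
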