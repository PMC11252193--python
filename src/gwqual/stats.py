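"""Descriptive statistics and Pearson correlation for survey cohorts.

``describe`` mirrors the classic hydrochemistry summary table
(min/max/mean/SD/CV%/skewness/kurtosis); kurtosis defaults to the Pearson
(raw, normal = 3) convention with a Fisher-excess flag. ``pearson_matrix``
returns r with two-sided p-values from the t distribution on n−2 df and
the usual 0.05 / 0.01 / 0.001 significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["DescriptiveRow", "CorrelationMatrix", "describe", "pearson_matrix",
           "correlation_pairs", "PARAMETER_COLUMNS"]

#: default column set summarized by the pipeline
PARAMETER_COLUMNS = ["pH", "EC_uScm", "TDS_mgL", "Na_mgL", "K_mgL", "Mg_mgL",
                     "Ca_mgL", "F_mgL", "Cl_mgL", "SO4_mgL", "HCO3_mgL",
                     "CO3_mgL", "NO3_mgL", "Hardness_mgL", "Turbidity_NTU"]


@dataclass
class DescriptiveRow:
    parameter: str
    n: int
    min: float
    max: float
    mean: float
    sd: float
    cv_percent: float
    skewness: float
    kurtosis: float


@dataclass
class CorrelationMatrix:
    parameters: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def stars(self) -> pd.DataFrame:
        def star(p: float) -> str:
            if p < 0.001:
                return "***"
            if p < 0.01:
                return "**"
            if p < 0.05:
                return "*"
            return ""
        return self.p.map(star)


def describe(df: pd.DataFrame, parameters: list[str] | None = None,
             fisher: bool = False) -> pd.DataFrame:
    """Summary table; sample SD (ddof=1), bias-uncorrected g1 skewness,
    raw kurtosis (normal = 3) unless ``fisher`` requests excess kurtosis.
    CV% is 100·SD/mean (NaN when the mean is zero)."""
    parameters = parameters or [c for c in PARAMETER_COLUMNS if c in df.columns]
    rows = []
    for p in parameters:
        x = pd.to_numeric(df[p], errors="raise").dropna().to_numpy(float)
        if x.size < 2:
            raise ValueError(f"{p}: need at least 2 observations, got {x.size}")
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        kurt = float(sps.kurtosis(x, fisher=fisher, bias=True))
        rows.append(DescriptiveRow(
            parameter=p, n=int(x.size), min=float(np.min(x)), max=float(np.max(x)),
            mean=mean, sd=sd,
            cv_percent=100.0 * sd / mean if mean != 0 else float("nan"),
            skewness=float(sps.skew(x, bias=True)),
            kurtosis=kurt,
        ).__dict__)
    return pd.DataFrame(rows)


def pearson_matrix(df: pd.DataFrame, parameters: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise-complete Pearson r with two-sided t-test p-values.

    A zero-variance parameter yields r = NaN for its pairs and is reported
    (flagged) rather than silently propagated: its p-values are set to NaN
    too, and the caller can drop the row.
    """
    parameters = parameters or [c for c in PARAMETER_COLUMNS if c in df.columns]
    sub = df[parameters].apply(pd.to_numeric, errors="raise")
    n = len(sub)
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    k = len(parameters)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = sub.iloc[:, [i, j]].dropna()
            x, y = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
            if x.std(ddof=1) == 0 or y.std(ddof=1) == 0 or len(x) < 3:
                rij, pij = np.nan, np.nan
            else:
                res = sps.pearsonr(x, y)
                rij, pij = float(res.statistic), float(res.pvalue)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rdf = pd.DataFrame(r, index=parameters, columns=parameters)
    pdf = pd.DataFrame(p, index=parameters, columns=parameters)
    return CorrelationMatrix(parameters, rdf, pdf, n)


def correlation_pairs(cm: CorrelationMatrix) -> pd.DataFrame:
    """Flat (param_a, param_b, r, p, stars) listing of the upper triangle."""
    stars = cm.stars()
    rows = []
    for i, a in enumerate(cm.parameters):
        for b in cm.parameters[i + 1:]:
            rows.append({"param_a": a, "param_b": b,
                         "r": cm.r.loc[a, b], "p": cm.p.loc[a, b],
                         "stars": stars.loc[a, b]})
    return pd.DataFrame(rows)
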