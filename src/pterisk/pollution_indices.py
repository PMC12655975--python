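"""Pollution and ecological risk indices with their category schemes.

Implements the single pollution index PI = C/S, the Nemerow comprehensive
index NI = sqrt((max(PI)² + mean(PI)²)/2), the Hakanson single ecological
risk index EI = T_r · PI and its sum PERI, the standard category schemes for
each, and the Table-1-style descriptive statistics (mean, max, min, sample
SD, skewness, CV%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import ReferenceBundle, SampleTable

__all__ = [
    "StatsRow",
    "IndexResult",
    "descriptive_stats",
    "single_pollution_index",
    "nemerow_index",
    "ecological_index",
    "classify",
    "index_table",
    "category_shares",
]


@dataclass
class StatsRow:
    """Descriptive statistics for one element in one medium."""

    element: str
    mean: float
    max: float
    min: float
    sd: float
    skewness: float

    @property
    def cv_percent(self) -> float:
        """Coefficient of variation, 100·SD/mean (full precision)."""
        if self.mean <= 0:
            return float("nan") if self.sd > 0 else 0.0
        return 100.0 * self.sd / self.mean

    @property
    def cv_display(self) -> int:
        """CV% rounded to the nearest integer, halves away from zero."""
        return int(math.floor(self.cv_percent + 0.5))


@dataclass
class IndexResult:
    """Per-site pollution and ecological risk indices."""

    site: str
    pi: dict[str, float]
    ni: float
    ei: dict[str, float] = field(default_factory=dict)
    peri: float = 0.0
    categories: dict[str, str] = field(default_factory=dict)


def descriptive_stats(samples: SampleTable) -> list[StatsRow]:
    """Per-element mean/max/min/sample SD/skewness over sites.

    SD uses the n−1 denominator; skewness is the adjusted Fisher–Pearson
    standardized moment coefficient (the convention of common spreadsheet
    output). A constant column has SD 0 and skewness reported as 0.
    """
    if samples.n_sites < 2:
        raise ValueError("descriptive statistics require at least 2 sites (sample SD undefined)")
    rows = []
    for el in samples.elements:
        x = samples.values[el].to_numpy(dtype=float)
        sd = float(np.std(x, ddof=1))
        skew = float(sps.skew(x, bias=False)) if sd > 0 else 0.0
        rows.append(
            StatsRow(
                element=el,
                mean=float(np.mean(x)),
                max=float(np.max(x)),
                min=float(np.min(x)),
                sd=sd,
                skewness=skew,
            )
        )
    return rows


def single_pollution_index(c: float, s: float) -> float:
    """PI = measured concentration over screening/background value."""
    if s <= 0:
        raise ValueError(f"screening value must be > 0, got {s}")
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    return c / s


def nemerow_index(pis) -> float:
    """NI = sqrt((max(PI)² + mean(PI)²)/2), weighting the worst element."""
    pis = np.asarray(list(pis), dtype=float)
    if pis.size == 0:
        raise ValueError("Nemerow index requires at least one PI")
    if (pis < 0).any():
        raise ValueError("PI values must be non-negative")
    return float(np.sqrt((pis.max() ** 2 + pis.mean() ** 2) / 2.0))


def ecological_index(pi: float, tr: float) -> float:
    """EI = T_r · PI; PERI for a site is the sum over configured elements."""
    if tr <= 0:
        raise ValueError(f"toxicity coefficient must be > 0, got {tr}")
    return pi * tr


# Category schemes. PI/NI interior boundaries belong to the lower class
# (intervals left-open/right-closed: "safe (<=1), alert (1-2), ...");
# EI/PERI boundaries belong to the upper class ("low (<40), moderate
# (40-80), ... extremely high (>=320)").
_SCHEMES: dict[str, tuple[list[float], list[str], str]] = {
    "PI": ([1.0, 2.0, 3.0, 5.0], ["safe", "alert", "slight", "moderate", "severe"], "lower"),
    "NI": ([0.7, 1.0, 2.0, 3.0], ["safe", "alert", "slight", "moderate", "severe"], "lower"),
    "EI": (
        [40.0, 80.0, 160.0, 320.0],
        ["low", "moderate", "considerable", "high", "extremely high"],
        "upper",
    ),
    "PERI": (
        [150.0, 300.0, 600.0, 1200.0],
        ["low", "moderate", "considerable", "high", "extremely high"],
        "upper",
    ),
}


def classify(value: float, scheme: str) -> str:
    """Map an index value to its category label under the named scheme."""
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown classification scheme {scheme!r}")
    if value < 0 or not np.isfinite(value):
        raise ValueError(f"index value must be finite and >= 0, got {value}")
    bounds, labels, side = _SCHEMES[scheme]
    for i, b in enumerate(bounds):
        if (side == "lower" and value <= b) or (side == "upper" and value < b):
            return labels[i]
    return labels[-1]


def index_table(samples: SampleTable, refs: ReferenceBundle) -> pd.DataFrame:
    """Per-site PI/EI per element plus NI and PERI with category labels.

    Elements without a screening value for the medium (e.g. Mo and V in
    crops under the default bundle) are excluded from PI, NI, EI and PERI
    rather than erroring: absent criteria mean the element is not assessed.
    EI/PERI require toxicity coefficients and are reported only for elements
    that have them.
    """
    screening = refs.screening_for(samples.medium)
    assessed = [el for el in samples.elements if el in screening]
    if not assessed:
        raise ValueError(f"no screening values cover any element in medium {samples.medium.value}")
    rows = []
    for site in samples.sites:
        pi = {el: single_pollution_index(samples.values.loc[site, el], screening[el]) for el in assessed}
        ni = nemerow_index(pi.values())
        ei = {el: ecological_index(pi[el], refs.toxicity[el]) for el in assessed if el in refs.toxicity}
        peri = float(sum(ei.values()))
        row: dict[str, object] = {"site": site}
        for el in assessed:
            row[f"PI_{el}"] = pi[el]
            row[f"PI_{el}_category"] = classify(pi[el], "PI")
        row["NI"] = ni
        row["NI_category"] = classify(ni, "NI")
        for el, v in ei.items():
            row[f"EI_{el}"] = v
            row[f"EI_{el}_category"] = classify(v, "EI")
        row["PERI"] = peri
        row["PERI_category"] = classify(peri, "PERI")
        rows.append(row)
    return pd.DataFrame(rows).set_index("site")


def category_shares(table: pd.DataFrame, column: str) -> pd.Series:
    """Share of sites per category for one ``*_category`` column (sums to 1)."""
    if column not in table.columns:
        raise KeyError(f"no column {column!r} in index table")
    counts = table[column].value_counts()
    return counts / counts.sum()
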