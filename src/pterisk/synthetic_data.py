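"""Synthetic concentration tables with known source structure.

Two generators cover the two statistical features the pipeline relies on:

- :func:`generate_mixture` builds site × element tables from known source
  profiles (geogenic weathering, antimony mining, lead–zinc mining,
  agricultural inputs) mixed with gamma-distributed per-site weights and
  multiplicative lognormal noise — ground truth for parameter-recovery
  tests of the PCA source apportionment.
- :func:`mimic_table1` draws each element independently from a lognormal
  moment-matched to published per-element mean/SD targets, emulating the
  marginal structure (strong right skew, CV above 100 % in water) of
  survey data from a mining-impacted basin.

``STUDY_SUMMARY`` holds the published summary statistics (69 water, 79
soil, 79 crop samples from a mining-impacted river basin) used as default
targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ELEMENTS, Medium, SampleTable
from .pollution_indices import StatsRow

__all__ = [
    "SourceProfile",
    "SyntheticTruth",
    "STUDY_SUMMARY",
    "generate_mixture",
    "mimic_table1",
    "preset",
    "truth_loading_directions",
]

_SUMMARY_COLS = ["mean", "max", "min", "sd", "skewness", "cv"]

#: Published per-element summary statistics of PTE concentrations in a
#: mining-impacted river basin (water in μg/L, soil and crops in mg/kg dry
#: weight; CV printed as integer percent). Used as emulation targets for
#: :func:`mimic_table1` and as worked examples for CV recomputation.
STUDY_SUMMARY: dict[Medium, pd.DataFrame] = {
    Medium.surface_water: pd.DataFrame(
        {
            "Pb": [2.86, 42.10, 0.09, 8.17, 3.50, 286],
            "Cr": [1.22, 23.50, 0.11, 3.92, 5.03, 320],
            "Ni": [51.52, 2950.00, 0.06, 355.39, 8.21, 690],
            "Cu": [48.34, 2910.00, 0.56, 350.05, 8.27, 724],
            "Zn": [918.12, 31300.00, 0.67, 4214.48, 6.08, 459],
            "As": [1.57, 7.99, 0.12, 1.83, 1.99, 117],
            "Mo": [235.05, 3040.00, 0.12, 610.58, 3.30, 260],
            "Cd": [3.21, 63.70, 0.05, 11.35, 3.95, 353],
            "Sb": [21.91, 239.00, 0.15, 51.66, 2.75, 236],
            "V": [1.20, 7.40, 0.10, 1.34, 3.55, 112],
        },
        index=_SUMMARY_COLS,
    ).T,
    Medium.soil: pd.DataFrame(
        {
            "Pb": [21.79, 37.42, 1.91, 7.99, -0.03, 37],
            "Cr": [14.87, 19.85, 2.58, 3.34, -1.12, 22],
            "Ni": [7.85, 11.41, 1.78, 1.82, -0.67, 23],
            "Cu": [6.53, 9.27, 2.30, 1.50, -0.48, 23],
            "Zn": [16.58, 22.60, 5.67, 3.37, -0.83, 20],
            "As": [3.70, 7.43, 0.80, 1.26, 1.28, 34],
            "Mo": [0.73, 1.75, 0.07, 0.36, 0.70, 49],
            "Cd": [0.26, 0.76, 0.03, 0.16, 1.34, 63],
            "Sb": [9.62, 31.89, 1.32, 8.08, 1.03, 84],
            "V": [22.87, 30.06, 4.83, 4.70, -1.44, 21],
        },
        index=_SUMMARY_COLS,
    ).T,
    Medium.crop: pd.DataFrame(
        {
            "Pb": [1.10, 2.82, 0.03, 0.76, 0.55, 69],
            "Cr": [1.49, 3.83, 0.09, 0.95, 0.64, 64],
            "Ni": [0.80, 1.90, 0.05, 0.51, 0.47, 63],
            "Cu": [0.69, 1.62, 0.04, 0.39, 0.30, 57],
            "Zn": [2.32, 5.49, 0.15, 1.29, 0.26, 56],
            "As": [0.37, 1.10, 0.02, 0.22, 0.80, 61],
            "Mo": [0.004, 0.02, 0.0004, 0.021, 5.43, 527],
            "Cd": [0.01, 0.04, 0.001, 0.012, 1.37, 121],
            "Sb": [0.74, 2.92, 0.03, 0.78, 1.51, 105],
            "V": [1.88, 4.57, 0.15, 1.14, 0.48, 61],
        },
        index=_SUMMARY_COLS,
    ).T,
}


@dataclass
class SourceProfile:
    """One pollution source: per-element emission strength and a gamma
    distribution (shape, scale) for its per-site mixing weight."""

    label: str
    signature: dict[str, float]
    weight_shape: float = 2.0
    weight_scale: float = 1.0

    def __post_init__(self) -> None:
        if not any(v > 0 for v in self.signature.values()):
            raise ValueError(f"profile {self.label!r} has no positive signature entry")
        if any(v < 0 for v in self.signature.values()):
            raise ValueError(f"profile {self.label!r} has negative signature entries")
        if self.weight_shape <= 0 or self.weight_scale <= 0:
            raise ValueError("gamma mixing-weight parameters must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated table."""

    profiles: list[SourceProfile]
    mixing: pd.DataFrame  # site × source weights
    noise_cv: float
    seed: int
    warnings: list[str] = field(default_factory=list)


def _signature_matrix(profiles: list[SourceProfile], elements: list[str]) -> np.ndarray:
    return np.array([[p.signature.get(el, 0.0) for el in elements] for p in profiles])


def generate_mixture(
    profiles: list[SourceProfile],
    n_sites: int,
    noise_cv: float = 20.0,
    seed: int = 0,
    medium: Medium | str = Medium.soil,
    elements: tuple[str, ...] = ELEMENTS,
) -> tuple[SampleTable, SyntheticTruth]:
    """Mix source profiles into a concentration table with known truth.

    C_{s,i} = (Σ_k a_{s,k} · signature_{k,i}) · ε_{s,i}, with per-site
    weights a drawn from each profile's gamma distribution and ε lognormal
    with unit median and the given CV (percent). Linearly dependent
    signatures are flagged as a warning in the truth metadata, not an
    error.
    """
    k = len(profiles)
    if k == 0:
        raise ValueError("at least one source profile is required")
    if n_sites < 3 * k:
        raise ValueError(f"need n_sites >= 3 × number of profiles ({3 * k}), got {n_sites}")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")

    rng = np.random.default_rng(seed)
    elements = list(elements)
    sig = _signature_matrix(profiles, elements)  # k × m
    warns = []
    if np.linalg.matrix_rank(sig) < k:
        warns.append("source signatures are linearly dependent; recovery is not identifiable")

    a = np.column_stack(
        [rng.gamma(p.weight_shape, p.weight_scale, n_sites) for p in profiles]
    )  # n × k
    clean = a @ sig  # n × m
    if noise_cv > 0:
        cv = noise_cv / 100.0
        sigma = math.sqrt(math.log1p(cv * cv))
        eps = rng.lognormal(0.0, sigma, size=clean.shape)  # unit median
        values = clean * eps
    else:
        values = clean

    sites = [f"S{i + 1:03d}" for i in range(n_sites)]
    table = SampleTable(
        medium=Medium(medium),
        values=pd.DataFrame(values, index=sites, columns=elements),
    )
    truth = SyntheticTruth(
        profiles=list(profiles),
        mixing=pd.DataFrame(a, index=sites, columns=[p.label for p in profiles]),
        noise_cv=noise_cv,
        seed=seed,
        warnings=warns,
    )
    return table, truth


def mimic_table1(
    stats: list[StatsRow] | pd.DataFrame,
    n_sites: int,
    seed: int = 0,
    medium: Medium | str = Medium.soil,
) -> SampleTable:
    """Draw each element independently from a moment-matched lognormal.

    Targets are per-element arithmetic mean m and SD s; the lognormal
    parameters are μ = ln(m²/√(m²+s²)) and σ² = ln(1+s²/m²), so the
    distribution's arithmetic moments equal the targets. An SD of 0 yields
    a constant column at the mean. Elements are independent by design: this
    generator targets marginal moments only, correlation structure comes
    from :func:`generate_mixture`.
    """
    if isinstance(stats, pd.DataFrame):
        rows = [
            StatsRow(element=el, mean=r["mean"], max=np.inf, min=0.0, sd=r["sd"], skewness=0.0)
            for el, r in stats.iterrows()
        ]
    else:
        rows = list(stats)
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for row in rows:
        m, s = row.mean, row.sd
        if m <= 0:
            raise ValueError(f"target mean for {row.element} must be > 0")
        if s < 0:
            raise ValueError(f"target SD for {row.element} must be >= 0")
        if s == 0:
            cols[row.element] = np.full(n_sites, m)
            continue
        sigma2 = math.log1p((s / m) ** 2)
        mu = math.log(m) - 0.5 * sigma2
        cols[row.element] = rng.lognormal(mu, math.sqrt(sigma2), n_sites)
    sites = [f"S{i + 1:03d}" for i in range(n_sites)]
    return SampleTable(
        medium=Medium(medium),
        values=pd.DataFrame(cols, index=sites),
    )


# Presets mirror the source structure typical of a mining-impacted basin:
# a geogenic component (lithophile elements), mining signatures (Sb mining
# rich in As/Sb; Pb-Zn mining rich in Pb/Zn/Cd) and agricultural inputs
# (Cu/As from pesticides and herbicides). Dominant-element strengths are
# scaled so that mean concentrations (weight mean × strength) resemble the
# corresponding medium's survey means; every non-dominant element receives
# 5 % cross-contamination so sources overlap slightly, as real emission
# inventories do.
_PRESET_MEMBERSHIP: dict[str, tuple[Medium, list[tuple[str, list[str]]]]] = {
    "soil_3source": (
        Medium.soil,
        [
            ("geogenic", ["Cr", "Ni", "V"]),
            ("mining", ["Pb", "Zn", "Mo", "Cd", "Sb"]),
            ("agriculture", ["Cu", "As"]),
        ],
    ),
    "water_4source": (
        Medium.surface_water,
        [
            ("mining_upstream", ["Cr", "Ni", "Cu"]),
            ("mining_Sb", ["As", "Sb"]),
            ("mining_PbZn", ["Pb", "Zn", "Cd"]),
            ("geogenic", ["Mo", "V"]),
        ],
    ),
    "crop_2source": (
        Medium.crop,
        [
            ("agriculture", ["Pb", "Cr", "Ni", "Cu", "Zn", "As", "Cd", "V"]),
            ("mining", ["Mo", "Sb"]),
        ],
    ),
}

_CROSS_CONTAMINATION = 0.05


def preset(name: str) -> list[SourceProfile]:
    """Documented source-profile presets (see module docstring)."""
    if name not in _PRESET_MEMBERSHIP:
        raise ValueError(f"unknown preset {name!r}; known: {sorted(_PRESET_MEMBERSHIP)}")
    medium, membership = _PRESET_MEMBERSHIP[name]
    means = STUDY_SUMMARY[medium]["mean"]
    n_sources = len(membership)
    profiles = []
    for label, members in membership:
        signature = {}
        for el in ELEMENTS:
            # dominant strength: element mean / mean mixing weight (gamma
            # shape 2, scale 1 → mean 2); off-source: 5 % cross-contamination
            # split between the non-dominant sources
            strength = max(float(means[el]), 1e-6) / 2.0
            if el in members:
                signature[el] = strength
            else:
                signature[el] = _CROSS_CONTAMINATION * strength / (n_sources - 1) if n_sources > 1 else 0.0
        profiles.append(SourceProfile(label=label, signature=signature))
    return profiles


def truth_loading_directions(truth: SyntheticTruth, table: SampleTable) -> pd.DataFrame:
    """Each true source's direction in loading space.

    Returns the element × source matrix of Pearson correlations between the
    recorded per-site mixing weights and the generated concentrations —
    the pattern a correlation-matrix PCA should recover as a rotated
    loading vector. Used for cosine-similarity matching in recovery tests.
    """
    out = {}
    for label in truth.mixing.columns:
        a = truth.mixing[label].to_numpy()
        out[label] = {
            el: float(np.corrcoef(a, table.values[el].to_numpy())[0, 1])
            for el in table.elements
        }
    return pd.DataFrame(out)
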