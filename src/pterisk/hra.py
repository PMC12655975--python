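"""Deterministic USEPA-style health risk assessment.

Average daily intake (ADI, mg·kg⁻¹·day⁻¹) is computed per element and
pathway:

    ADI_ing = C · R_ing · EF · ED / (BW · AT) · unit_factor
    ADI_der = C · SA · AF · ABS · EF · ED / (BW · AT) · unit_factor
    ADI_inh = C · R_inh · EF · ED / (PEF · BW · AT)

Non-carcinogenic risk NRI = Σ ADI/RfD (threshold 1) and carcinogenic risk
CRI = Σ ADI·SF (threshold 1×10⁻⁴) are summed over elements and pathways.
All functions accept scalar or ndarray parameter values, so the Monte Carlo
engine reuses them vectorised over iterations.

Averaging time AT is ED·365 days for non-carcinogenic endpoints and a
70-year lifetime (25550 days) for carcinogenic endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import (
    Medium,
    Pathway,
    Population,
    ReferenceBundle,
    SampleTable,
)

__all__ = [
    "LIFETIME_YEARS",
    "ExposureParams",
    "RiskResult",
    "adi_ingestion",
    "adi_dermal",
    "adi_inhalation",
    "risk_indices",
    "assess_site",
    "assess_table",
]

NRI_THRESHOLD = 1.0
CRI_THRESHOLD = 1.0e-4
LIFETIME_YEARS = 70.0


@dataclass
class ExposureParams:
    """Exposure parameters for one population and medium.

    ``r_ing`` is the medium intake rate (mg/day for soil, L/day for water);
    ``r_inh`` the air inhalation rate (m³/day); ``ef`` exposure frequency
    (days/year); ``ed`` exposure duration (years); ``bw`` body weight (kg);
    ``sa`` exposed skin area (cm²); ``af`` soil-to-skin adherence
    (mg/cm²·day); ``abs_frac`` dermal absorption fraction; ``pef`` particle
    emission factor (m³/kg). ``r_inh``/``pef`` may be None when the
    inhalation pathway is not applicable (e.g. surface water). Fields may
    hold ndarrays for vectorised Monte Carlo evaluation.
    """

    r_ing: float | np.ndarray
    ef: float | np.ndarray
    ed: float | np.ndarray
    bw: float | np.ndarray
    sa: float | np.ndarray
    af: float | np.ndarray
    abs_frac: float | np.ndarray
    r_inh: Optional[float | np.ndarray] = None
    pef: Optional[float | np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("r_ing", "ef", "ed", "bw", "sa", "af", "abs_frac"):
            v = getattr(self, name)
            if np.any(np.asarray(v) <= 0):
                raise ValueError(f"exposure parameter {name} must be strictly positive")
        if np.any(np.asarray(self.abs_frac) > 1):
            raise ValueError("dermal absorption fraction must be in (0, 1]")
        for name in ("r_inh", "pef"):
            v = getattr(self, name)
            if v is not None and np.any(np.asarray(v) <= 0):
                raise ValueError(f"exposure parameter {name} must be strictly positive")

    @property
    def at_noncarcinogenic(self):
        return self.ed * 365.0

    @property
    def at_carcinogenic(self) -> float:
        return LIFETIME_YEARS * 365.0

    @classmethod
    def from_bundle(
        cls, refs: ReferenceBundle, population: Population | str, medium: Medium | str
    ) -> "ExposureParams":
        """Deterministic parameters: the central value of each distribution."""
        specs = refs.exposure_specs(Population(population), Medium(medium))
        vals = {name: spec.central() for name, spec in specs.items()}
        return cls(
            r_ing=vals["r_ing"],
            ef=vals["ef"],
            ed=vals["ed"],
            bw=vals["bw"],
            sa=vals["sa"],
            af=vals["af"],
            abs_frac=vals["abs"],
            r_inh=vals.get("r_inh"),
            pef=vals.get("pef"),
        )

    def with_abs(self, abs_frac: float | np.ndarray) -> "ExposureParams":
        return replace(self, abs_frac=abs_frac)


@dataclass
class RiskResult:
    """Per-site deterministic risk decomposition for one population.

    ``adi``/``nri_by`` are element × pathway DataFrames; ``cri_by`` holds
    only the (element, pathway) cells that have a slope factor — elements
    without one contribute to NRI only and are listed in
    ``elements_without_sf`` rather than zero-filled.
    """

    site: str
    population: Population
    medium: Medium
    adi: pd.DataFrame
    nri_by: pd.DataFrame
    cri_by: pd.DataFrame
    nri_total: float
    cri_total: float
    elements_without_sf: list[str]

    @property
    def nri_flag(self) -> bool:
        return self.nri_total > NRI_THRESHOLD

    @property
    def cri_flag(self) -> bool:
        return self.cri_total > CRI_THRESHOLD


def _check_pos(**kwargs) -> None:
    for name, v in kwargs.items():
        if np.any(np.asarray(v) <= 0):
            raise ValueError(f"{name} must be strictly positive")


def adi_ingestion(c, p: ExposureParams, at, unit_factor):
    """Intake via ingestion of the medium."""
    _check_pos(bw=p.bw, at=at, unit_factor=unit_factor)
    return c * p.r_ing * p.ef * p.ed / (p.bw * at) * unit_factor


def adi_dermal(c, p: ExposureParams, at, unit_factor):
    """Intake via dermal contact (skin area × adherence × absorption)."""
    _check_pos(bw=p.bw, at=at, unit_factor=unit_factor, abs_frac=p.abs_frac)
    return c * p.sa * p.af * p.abs_frac * p.ef * p.ed / (p.bw * at) * unit_factor


def adi_inhalation(c, p: ExposureParams, at):
    """Intake via inhalation of resuspended particles; no unit factor."""
    if p.r_inh is None or p.pef is None:
        raise ValueError("inhalation pathway requires r_inh and pef")
    _check_pos(bw=p.bw, at=at)
    return c * p.r_inh * p.ef * p.ed / (p.pef * p.bw * at)


def _pathway_adi(c, pathway: Pathway, p: ExposureParams, at, unit_factor):
    if pathway == Pathway.ingestion:
        return adi_ingestion(c, p, at, unit_factor)
    if pathway == Pathway.dermal:
        return adi_dermal(c, p, at, unit_factor)
    return adi_inhalation(c, p, at)


def available_pathways(p: ExposureParams) -> list[Pathway]:
    pws = [Pathway.ingestion, Pathway.dermal]
    if p.r_inh is not None and p.pef is not None:
        pws.append(Pathway.inhalation)
    return pws


def risk_indices(adi: pd.DataFrame, refs: ReferenceBundle) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """NRI and CRI cells from an element × pathway ADI table.

    NRI = ADI/RfD for every cell; a missing RfD with nonzero ADI is an
    error. CRI = ADI·SF only where a slope factor exists; elements with no
    slope factor at all are returned separately.
    """
    nri = pd.DataFrame(index=adi.index, columns=adi.columns, dtype=float)
    cri = pd.DataFrame(np.nan, index=adi.index, columns=adi.columns, dtype=float)
    no_sf = []
    for el in adi.index:
        el_rfd = refs.rfd.get(el, {})
        el_sf = refs.slope.get(el, {})
        if not el_sf:
            no_sf.append(el)
        for pw in adi.columns:
            pathway = Pathway(pw)
            a = adi.loc[el, pw]
            if pathway not in el_rfd:
                if np.any(np.asarray(a) != 0):
                    raise ValueError(f"missing reference dose for ({el}, {pathway.value})")
                nri.loc[el, pw] = 0.0
            else:
                nri.loc[el, pw] = a / el_rfd[pathway]
            if pathway in el_sf:
                cri.loc[el, pw] = a * el_sf[pathway]
    return nri, cri, no_sf


def assess_site(
    concentrations: pd.Series,
    refs: ReferenceBundle,
    population: Population | str,
    medium: Medium | str,
    site: str = "",
    params: ExposureParams | None = None,
) -> RiskResult:
    """Deterministic risk for one site (element → concentration Series)."""
    population = Population(population)
    medium = Medium(medium)
    p = params if params is not None else ExposureParams.from_bundle(refs, population, medium)
    uf = refs.unit_factor[medium]
    pathways = available_pathways(p)
    adi = pd.DataFrame(
        0.0, index=list(concentrations.index), columns=[pw.value for pw in pathways]
    )
    for el, c in concentrations.items():
        if c < 0:
            raise ValueError(f"negative concentration for {el}")
        p_el = p.with_abs(refs.abs_override[el]) if el in refs.abs_override else p
        for pw in pathways:
            adi.loc[el, pw.value] = _pathway_adi(c, pw, p_el, p_el.at_noncarcinogenic, uf)
    nri, _, _ = risk_indices(adi, refs)

    # carcinogenic endpoint uses lifetime averaging, so ADI is recomputed
    adi_ca = pd.DataFrame(0.0, index=adi.index, columns=adi.columns)
    for el, c in concentrations.items():
        p_el = p.with_abs(refs.abs_override[el]) if el in refs.abs_override else p
        for pw in pathways:
            adi_ca.loc[el, pw.value] = _pathway_adi(c, pw, p_el, p_el.at_carcinogenic, uf)
    _, cri, no_sf = risk_indices(adi_ca, refs)

    return RiskResult(
        site=site,
        population=population,
        medium=medium,
        adi=adi,
        nri_by=nri,
        cri_by=cri,
        nri_total=float(nri.to_numpy().sum()),
        cri_total=float(np.nansum(cri.to_numpy())),
        elements_without_sf=no_sf,
    )


def assess_table(
    samples: SampleTable,
    refs: ReferenceBundle,
    population: Population | str,
) -> dict[str, RiskResult]:
    """Deterministic risk for every site of a sample table."""
    return {
        site: assess_site(
            samples.values.loc[site], refs, population, samples.medium, site=site
        )
        for site in samples.sites
    }


def risk_frame(results: dict[str, RiskResult]) -> pd.DataFrame:
    """Long-format site/element/pathway ADI-NRI-CRI table for reporting."""
    rows = []
    for site, r in results.items():
        for el in r.adi.index:
            for pw in r.adi.columns:
                rows.append(
                    {
                        "site": site,
                        "population": r.population.value,
                        "element": el,
                        "pathway": pw,
                        "adi": r.adi.loc[el, pw],
                        "nri": r.nri_by.loc[el, pw],
                        "cri": r.cri_by.loc[el, pw],
                    }
                )
    return pd.DataFrame(rows)
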