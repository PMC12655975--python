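"""Domain types and I/O for concentration tables and reference configuration.

The pipeline works on three environmental media — surface water (μg/L),
agricultural soil and crop edible tissue (both mg/kg dry weight) — each
represented as a site × element concentration matrix (:class:`SampleTable`).
Screening values, toxicity response coefficients, reference doses, slope
factors and exposure-parameter distributions live in a
:class:`ReferenceBundle` loaded from a YAML config; a default bundle with
conventional literature values ships with the package.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "Medium",
    "Pathway",
    "Population",
    "ELEMENTS",
    "SampleTable",
    "DistributionSpec",
    "ReferenceBundle",
    "ValidationReport",
    "load_samples",
    "write_samples",
    "load_reference_bundle",
    "default_reference_bundle",
    "validate",
]

#: Canonical element order used throughout the package.
ELEMENTS = ("Pb", "Cr", "Ni", "Cu", "Zn", "As", "Mo", "Cd", "Sb", "V")


class Medium(str, enum.Enum):
    surface_water = "surface_water"
    soil = "soil"
    crop = "crop"


class Pathway(str, enum.Enum):
    ingestion = "ingestion"
    dermal = "dermal"
    inhalation = "inhalation"


class Population(str, enum.Enum):
    adult = "adult"
    child = "child"


#: Expected concentration unit per medium (soil/crop are dry weight).
MEDIUM_UNITS = {
    Medium.surface_water: "ug/L",
    Medium.soil: "mg/kg",
    Medium.crop: "mg/kg",
}

_UNIT_ALIASES = {"μg/l": "ug/L", "ug/l": "ug/L", "mg/kg": "mg/kg", "mg/kg dw": "mg/kg"}


def _canon_unit(unit: str) -> str:
    u = _UNIT_ALIASES.get(unit.strip().lower())
    if u is None:
        raise ValueError(f"unrecognised concentration unit {unit!r}")
    return u


@dataclass
class SampleTable:
    """Site × element concentration matrix for one environmental medium.

    ``values`` is indexed by site identifier with one column per element
    symbol. ``bdl_flags`` marks cells reported below the detection limit;
    the stored value for such a cell is the substituted value (DL/2 by
    default) and the per-element limit is kept in ``detection_limits`` so
    the table round-trips losslessly.
    """

    medium: Medium
    values: pd.DataFrame
    bdl_flags: Optional[pd.DataFrame] = None
    detection_limits: dict[str, float] = field(default_factory=dict)
    unit: str = ""

    def __post_init__(self) -> None:
        self.medium = Medium(self.medium)
        if not self.unit:
            self.unit = MEDIUM_UNITS[self.medium]
        self.unit = _canon_unit(self.unit)
        if self.unit != MEDIUM_UNITS[self.medium]:
            raise ValueError(
                f"unit {self.unit!r} inconsistent with medium {self.medium.value}"
                f" (expected {MEDIUM_UNITS[self.medium]!r})"
            )
        cols = list(self.values.columns)
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"duplicate element columns: {dupes}")
        self.values = self.values.astype(float)
        if (self.values.to_numpy() < 0).any():
            bad = self.values.columns[(self.values < 0).any()].tolist()
            raise ValueError(f"negative concentrations in columns {bad}")
        if self.values.isna().any().any():
            raise ValueError("concentration matrix contains missing cells")
        if self.bdl_flags is None:
            self.bdl_flags = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        else:
            self.bdl_flags = self.bdl_flags.reindex_like(self.values).fillna(False).astype(bool)
            flagged = self.bdl_flags.any()
            missing_dl = [c for c in self.values.columns[flagged] if c not in self.detection_limits]
            if missing_dl:
                raise ValueError(f"BDL flags without detection limits for {missing_dl}")

    @property
    def sites(self) -> list[str]:
        return list(self.values.index)

    @property
    def elements(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_sites(self) -> int:
        return len(self.values.index)

    def subset_elements(self, elements: list[str]) -> "SampleTable":
        missing = [e for e in elements if e not in self.values.columns]
        if missing:
            raise KeyError(f"elements not in table: {missing}")
        return SampleTable(
            medium=self.medium,
            values=self.values[elements].copy(),
            bdl_flags=self.bdl_flags[elements].copy(),
            detection_limits={e: v for e, v in self.detection_limits.items() if e in elements},
            unit=self.unit,
        )


class DistributionSpec(BaseModel):
    """Parametric distribution for an exposure parameter.

    ``kind`` selects the family; ``params`` are family-specific:

    - ``point``: ``value``
    - ``normal``: ``mean``, ``sd``
    - ``lognormal``: arithmetic ``mean`` and ``sd`` (moment-matched to the
      underlying log-scale parameters)
    - ``uniform``: ``low``, ``high``
    - ``triangular``: ``left``, ``mode``, ``right``

    Optional truncation bounds are enforced by rejection sampling.
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["point", "normal", "lognormal", "uniform", "triangular"]
    params: dict[str, float]
    truncation: Optional[tuple[Optional[float], Optional[float]]] = None

    @model_validator(mode="after")
    def _check(self) -> "DistributionSpec":
        p = self.params
        required = {
            "point": {"value"},
            "normal": {"mean", "sd"},
            "lognormal": {"mean", "sd"},
            "uniform": {"low", "high"},
            "triangular": {"left", "mode", "right"},
        }[self.kind]
        if set(p) != required:
            raise ValueError(f"{self.kind} spec needs params {sorted(required)}, got {sorted(p)}")
        if self.kind in ("normal", "lognormal") and p["sd"] <= 0:
            raise ValueError(f"{self.kind} scale must be positive")
        if self.kind == "lognormal" and p["mean"] <= 0:
            raise ValueError("lognormal mean must be positive")
        if self.kind == "uniform" and not p["low"] <= p["high"]:
            raise ValueError("uniform requires low <= high")
        if self.kind == "triangular" and not p["left"] <= p["mode"] <= p["right"]:
            raise ValueError("triangular requires left <= mode <= right")
        if self.truncation is not None:
            lo, hi = self.truncation
            if lo is not None and hi is not None and not lo < hi:
                raise ValueError("truncation requires lower < upper")
        return self

    def central(self) -> float:
        """Central (mean, ignoring truncation) value used by deterministic runs."""
        p = self.params
        if self.kind == "point":
            return p["value"]
        if self.kind in ("normal", "lognormal"):
            return p["mean"]
        if self.kind == "uniform":
            return 0.5 * (p["low"] + p["high"])
        return (p["left"] + p["mode"] + p["right"]) / 3.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.kind == "point":
            return np.full(n, p["value"])

        def draw(k: int) -> np.ndarray:
            if self.kind == "normal":
                return rng.normal(p["mean"], p["sd"], k)
            if self.kind == "lognormal":
                m, s = p["mean"], p["sd"]
                sigma2 = math.log1p((s / m) ** 2)
                mu = math.log(m) - 0.5 * sigma2
                return rng.lognormal(mu, math.sqrt(sigma2), k)
            if self.kind == "uniform":
                return rng.uniform(p["low"], p["high"], k)
            return rng.triangular(p["left"], p["mode"], p["right"], k)

        out = draw(n)
        if self.truncation is None:
            return out
        lo, hi = self.truncation
        lo = -np.inf if lo is None else lo
        hi = np.inf if hi is None else hi
        ok = (out > lo) & (out < hi)
        tries = 0
        while not ok.all():
            k = int((~ok).sum())
            fresh = draw(max(k * 4, 16))
            fresh = fresh[(fresh > lo) & (fresh < hi)][:k]
            if fresh.size:
                out[np.flatnonzero(~ok)[: fresh.size]] = fresh
                ok = (out > lo) & (out < hi)
            tries += 1
            if tries > 1000:
                raise ValueError(
                    f"truncation bounds ({lo}, {hi}) exclude essentially all mass of {self.kind}"
                )
        return out


class ReferenceBundle(BaseModel):
    """Screening values, toxicity weights, dose-response and exposure config.

    ``screening`` maps medium → element → screening/background value in the
    medium's own unit; ``toxicity`` holds Hakanson toxicity response
    coefficients; ``rfd``/``slope`` map element → pathway → RfD (mg/kg/day)
    and cancer slope factor ((mg/kg/day)⁻¹), with absent entries meaning the
    element is not assessed for that endpoint/pathway; ``exposure`` maps
    population → medium → parameter name → :class:`DistributionSpec`;
    ``unit_factor`` converts a raw concentration in the medium's unit to the
    mg-based quantity the intake equations expect (1e-6 for mg/kg soil since
    intake rates are in mg of soil; 1e-3 for μg/L water since intake rates
    are in L); ``abs_override`` gives element-specific dermal absorption
    fractions.
    """

    model_config = ConfigDict(frozen=True)

    screening: dict[Medium, dict[str, float]]
    toxicity: dict[str, float]
    rfd: dict[str, dict[Pathway, float]]
    slope: dict[str, dict[Pathway, float]] = Field(default_factory=dict)
    exposure: dict[Population, dict[Medium, dict[str, DistributionSpec]]]
    unit_factor: dict[Medium, float]
    abs_override: dict[str, float] = Field(default_factory=dict)

    @field_validator("screening")
    @classmethod
    def _screening_positive(cls, v):
        for medium, table in v.items():
            for el, s in table.items():
                if s <= 0:
                    raise ValueError(f"screening value for {el} in {Medium(medium).value} must be > 0")
        return v

    @field_validator("rfd")
    @classmethod
    def _rfd_positive(cls, v):
        for el, table in v.items():
            for pw, rd in table.items():
                if rd <= 0:
                    raise ValueError(f"reference dose for ({el}, {Pathway(pw).value}) must be > 0")
        return v

    @field_validator("slope")
    @classmethod
    def _slope_nonneg(cls, v):
        for el, table in v.items():
            for pw, sf in table.items():
                if sf < 0:
                    raise ValueError(f"slope factor for ({el}, {Pathway(pw).value}) must be >= 0")
        return v

    def toxicity_warnings(self) -> list[str]:
        return [
            f"toxicity coefficient for {el} is {tr} (< 1 is unusual for Hakanson coefficients)"
            for el, tr in self.toxicity.items()
            if tr < 1
        ]

    def screening_for(self, medium: Medium) -> dict[str, float]:
        return dict(self.screening.get(Medium(medium), {}))

    def exposure_specs(self, population: Population, medium: Medium) -> dict[str, DistributionSpec]:
        try:
            return dict(self.exposure[Population(population)][Medium(medium)])
        except KeyError as exc:
            raise KeyError(
                f"no exposure parameters configured for ({Population(population).value}, "
                f"{Medium(medium).value})"
            ) from exc


@dataclass
class ValidationReport:
    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.errors

    def add_error(self, location: str, message: str) -> None:
        self.errors.append((location, message))

    def add_warning(self, location: str, message: str) -> None:
        self.warnings.append((location, message))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"passed: {self.passed}"]
        lines += [f"ERROR   {loc}: {msg}" for loc, msg in self.errors]
        lines += [f"WARNING {loc}: {msg}" for loc, msg in self.warnings]
        return "\n".join(lines)


def load_samples(
    path: str | Path,
    medium: Medium | str,
    *,
    required_elements: tuple[str, ...] | None = ELEMENTS,
    detection_limits: dict[str, float] | None = None,
    bdl_policy: Literal["half", "zero", "dl"] = "half",
) -> SampleTable:
    """Read a delimited site × element concentration table.

    The file must have a header row with a site-identifier column (named
    ``site``, case-insensitive) followed by one column per element symbol.
    Comma and tab delimiters are accepted. Cells written as ``<X`` are
    below-detection-limit entries with detection limit ``X``; cells at or
    below a configured per-element detection limit are flagged likewise.
    Substitution follows ``bdl_policy``: half the limit (default), zero, or
    the limit itself.
    """
    medium = Medium(medium)
    path = Path(path)
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    raw.columns = [str(c).strip() for c in raw.columns]
    site_cols = [c for c in raw.columns if c.lower() == "site"]
    if not site_cols:
        raise ValueError(f"{path}: no 'site' column in header {list(raw.columns)}")
    raw = raw.set_index(site_cols[0])
    raw.index = raw.index.astype(str)

    if required_elements is not None:
        missing = [e for e in required_elements if e not in raw.columns]
        if missing:
            raise ValueError(f"{path}: missing element columns: {missing}")

    dls: dict[str, float] = dict(detection_limits or {})
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    flags = pd.DataFrame(False, index=raw.index, columns=raw.columns)
    for col in raw.columns:
        for site, cell in raw[col].items():
            text = str(cell).strip()
            if text.startswith("<"):
                try:
                    dl = float(text[1:])
                except ValueError as exc:
                    raise ValueError(f"{path}: unparseable BDL cell {text!r} at ({site}, {col})") from exc
                if col in dls and not math.isclose(dls[col], dl, rel_tol=1e-9):
                    raise ValueError(
                        f"{path}: conflicting detection limits for {col}: {dls[col]} vs {dl}"
                    )
                dls[col] = dl
                values.loc[site, col] = _substitute(dl, bdl_policy)
                flags.loc[site, col] = True
                continue
            try:
                v = float(text)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric cell {text!r} at ({site}, {col}) without BDL marker"
                ) from exc
            if v < 0:
                raise ValueError(f"{path}: negative concentration {v} at ({site}, {col})")
            if col in dls and v <= dls[col]:
                values.loc[site, col] = _substitute(dls[col], bdl_policy)
                flags.loc[site, col] = True
            else:
                values.loc[site, col] = v

    return SampleTable(
        medium=medium,
        values=values,
        bdl_flags=flags,
        detection_limits=dls,
        unit=MEDIUM_UNITS[medium],
    )


def _substitute(dl: float, policy: str) -> float:
    if policy == "half":
        return dl / 2.0
    if policy == "zero":
        return 0.0
    if policy == "dl":
        return dl
    raise ValueError(f"unknown BDL policy {policy!r}")


def write_samples(table: SampleTable, path: str | Path) -> None:
    """Write a :class:`SampleTable` as CSV, preserving BDL cells as ``<DL``.

    Values are written with full (repr) precision so that a write/read
    round-trip reproduces the table bit-identically.
    """
    path = Path(path)
    out = pd.DataFrame(index=table.values.index, columns=table.values.columns, dtype=object)
    for col in table.values.columns:
        for site in table.values.index:
            if table.bdl_flags.loc[site, col]:
                out.loc[site, col] = f"<{table.detection_limits[col]!r}"
            else:
                out.loc[site, col] = repr(float(table.values.loc[site, col]))
    out.index.name = "site"
    out.to_csv(path, encoding="utf-8")


def _parse_spec(node) -> DistributionSpec:
    if isinstance(node, (int, float, str)):
        return DistributionSpec(kind="point", params={"value": float(node)})
    kind = node["kind"]
    params = {k: float(v) for k, v in node.items() if k not in ("kind", "truncation")}
    trunc = node.get("truncation")
    if trunc is not None:
        trunc = (
            None if trunc[0] is None else float(trunc[0]),
            None if trunc[1] is None else float(trunc[1]),
        )
    return DistributionSpec(kind=kind, params=params, truncation=trunc)


def load_reference_bundle(path: str | Path) -> ReferenceBundle:
    """Load a :class:`ReferenceBundle` from a YAML config file.

    The schema mirrors the bundle fields: top-level keys ``screening``,
    ``toxicity``, ``rfd``, ``slope``, ``exposure``, ``unit_factor`` and
    optionally ``abs_override``. Exposure parameter entries may be bare
    numbers (shorthand for point distributions) or mappings with a ``kind``
    key and family-specific parameters.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _bundle_from_dict(doc, source=str(path))


def _bundle_from_dict(doc: dict, source: str = "<config>") -> ReferenceBundle:
    try:
        exposure = {
            pop: {
                med: {name: _parse_spec(node) for name, node in params.items()}
                for med, params in media.items()
            }
            for pop, media in doc["exposure"].items()
        }
        return ReferenceBundle(
            screening=doc["screening"],
            toxicity=doc["toxicity"],
            rfd=doc["rfd"],
            slope=doc.get("slope", {}),
            exposure=exposure,
            unit_factor=doc["unit_factor"],
            abs_override=doc.get("abs_override", {}),
        )
    except KeyError as exc:
        raise ValueError(f"{source}: missing required config section {exc}") from exc


def default_reference_bundle() -> ReferenceBundle:
    """The bundle shipped with the package (conventional literature values).

    Screening values are surface-water Class III limits, regional soil
    backgrounds and food contaminant limits; toxicity coefficients follow
    Hakanson with literature extensions for Sb/Mo/V; RfDs and slope factors
    are conventional risk-assessment values. All are replaceable defaults —
    supply a site-specific YAML via :func:`load_reference_bundle` for real
    assessments.
    """
    ref = resources.files("pterisk").joinpath("data/default_reference.yaml")
    with resources.as_file(ref) as p:
        return load_reference_bundle(p)


def validate(samples: SampleTable, refs: ReferenceBundle) -> ValidationReport:
    """Cross-check a sample table against a reference bundle.

    Findings are returned in a :class:`ValidationReport`, never raised;
    inputs are not mutated.
    """
    report = ValidationReport()
    medium = samples.medium
    if samples.unit != MEDIUM_UNITS[medium]:
        report.add_error(
            f"table[{medium.value}]",
            f"unit {samples.unit!r} inconsistent with medium (expected {MEDIUM_UNITS[medium]!r})",
        )
    screening = refs.screening_for(medium)
    for el in samples.elements:
        if el not in screening:
            report.add_error(
                f"screening[{medium.value}]",
                f"no screening value for element {el}",
            )
        if el not in refs.toxicity:
            report.add_warning("toxicity", f"no toxicity coefficient for element {el}")
        if el not in refs.rfd:
            report.add_warning("rfd", f"no reference doses for element {el}")
    for loc in refs.toxicity_warnings():
        report.add_warning("toxicity", loc)
    if (samples.values.to_numpy() < 0).any():
        report.add_error(f"table[{medium.value}]", "negative concentrations present")
    for el, dl in samples.detection_limits.items():
        if dl <= 0:
            report.add_error("detection_limits", f"non-positive detection limit for {el}")
    return report
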