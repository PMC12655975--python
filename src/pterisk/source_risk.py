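"""Source-to-risk attribution: couple PCA sources to health risk shares.

Element-level shares of total non-carcinogenic (NP) and carcinogenic (CP)
risk are combined with the element-to-source contribution matrix M to give
each source's percent contribution to the risk indices:

    NQ_k = Σ_i M_{i,k} · NP_i        CQ_k = Σ_i M_{i,k} · CP_i

Because M rows and the share vectors each sum to 1, NQ and CQ sum to 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hra import RiskResult
from .mc_engine import MCResult

__all__ = ["RiskShareVector", "SourceRiskResult", "element_risk_shares", "source_risk_contributions"]


@dataclass
class RiskShareVector:
    """Element shares of total NRI (``np_``) and CRI (``cp``), each summing to 1.

    ``cp`` covers only elements possessing slope factors; it is empty when no
    element carries carcinogenic risk.
    """

    np_: pd.Series
    cp: pd.Series


@dataclass
class SourceRiskResult:
    """Percent contribution of each source to NRI (``nq``) and CRI (``cq``)."""

    nq: pd.Series
    cq: pd.Series


def _shares_from_frames(nri: pd.DataFrame, cri: pd.DataFrame) -> RiskShareVector:
    nri_by_el = nri.sum(axis=0)
    total_nri = float(nri_by_el.sum())
    if total_nri <= 0:
        raise ValueError("total non-carcinogenic risk is zero; shares undefined")
    np_share = nri_by_el / total_nri

    cri_by_el = cri.sum(axis=0, min_count=1).dropna()
    total_cri = float(cri_by_el.sum()) if len(cri_by_el) else 0.0
    cp_share = cri_by_el / total_cri if total_cri > 0 else pd.Series(dtype=float)
    return RiskShareVector(np_=np_share, cp=cp_share)


def element_risk_shares(results: dict[str, RiskResult] | dict[str, MCResult]) -> RiskShareVector:
    """Element shares of basin-total risk, summed over sites and pathways.

    Accepts either deterministic per-site results or Monte Carlo results
    (in which case per-element mean risks are used). Aggregation across
    sites precedes the share computation.
    """
    if not results:
        raise ValueError("no site results supplied")
    first = next(iter(results.values()))
    if isinstance(first, MCResult):
        nri = pd.DataFrame({site: r.element_means["nri"] for site, r in results.items()}).T
        cri = pd.DataFrame({site: r.element_means["cri"] for site, r in results.items()}).T
    else:
        nri = pd.DataFrame({site: r.nri_by.sum(axis=1) for site, r in results.items()}).T
        cri = pd.DataFrame(
            {site: r.cri_by.sum(axis=1, min_count=1) for site, r in results.items()}
        ).T
    return _shares_from_frames(nri, cri)


def source_risk_contributions(m_matrix: pd.DataFrame, shares: RiskShareVector) -> SourceRiskResult:
    """Percent contribution of each source to total NRI and CRI.

    The elements of ``m_matrix`` must cover the share vectors exactly; CP
    elements are a subset of NP elements (slope factors are not universal),
    so CQ is renormalised over the covered subset by construction of CP.
    """
    m_elements = set(m_matrix.index)
    np_elements = set(shares.np_.index)
    if m_elements != np_elements:
        missing = sorted(np_elements - m_elements)
        extra = sorted(m_elements - np_elements)
        raise ValueError(
            f"element mismatch between M and risk shares: missing from M {missing}, "
            f"absent from shares {extra}"
        )
    nq = 100.0 * m_matrix.mul(shares.np_, axis=0).sum(axis=0)
    if len(shares.cp):
        cq = 100.0 * m_matrix.loc[shares.cp.index].mul(shares.cp, axis=0).sum(axis=0)
    else:
        cq = pd.Series(np.nan, index=m_matrix.columns)
    return SourceRiskResult(nq=nq, cq=cq)
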