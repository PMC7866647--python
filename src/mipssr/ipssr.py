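"""Revised International Prognostic Scoring System (IPSS-R) calculator.

The IPSS-R scores five components of a myelodysplastic-syndrome workup —
cytogenetics, bone-marrow blast percentage, hemoglobin, platelet count and
absolute neutrophil count (ANC) — on a half-point grid and sums them into a
0-10 total that maps onto five risk categories (very low ... very high).
"""

from __future__ import annotations

from dataclasses import dataclass

from .karyotype import CytoCategory

__all__ = [
    "IPSSR_CATEGORIES",
    "ClinicalComponents",
    "IPSSRResult",
    "ipssr_category",
    "ipssr_total",
    "score_anc",
    "score_blasts",
    "score_hemoglobin",
    "score_platelets",
]

IPSSR_CATEGORIES = ("very_low", "low", "intermediate", "high", "very_high")


@dataclass(frozen=True)
class ClinicalComponents:
    """The five IPSS-R inputs for one patient.

    Units: hemoglobin g/dL, platelets 10^9/L, ANC 10^9/L, blasts % of
    bone-marrow cells; ``cyto`` is the IPSS-R cytogenetic risk group.
    """

    hemoglobin: float
    platelets: float
    anc: float
    blasts: float
    cyto: CytoCategory

    def __post_init__(self) -> None:
        problems = []
        if not self.hemoglobin > 0:
            problems.append(f"hemoglobin must be > 0 g/dL, got {self.hemoglobin}")
        if self.platelets < 0:
            problems.append(f"platelets must be >= 0, got {self.platelets}")
        if self.anc < 0:
            problems.append(f"ANC must be >= 0, got {self.anc}")
        if not 0 <= self.blasts <= 100:
            problems.append(f"blasts must be in [0, 100] %, got {self.blasts}")
        if problems:
            raise ValueError("; ".join(problems))


@dataclass(frozen=True)
class IPSSRResult:
    points_cyto: float
    points_blasts: float
    points_hgb: float
    points_plt: float
    points_anc: float
    total: float
    category: str


def score_blasts(blasts: float) -> float:
    """Bone-marrow blast points: <=2% -> 0; >2-<5 -> 1; 5-10 -> 2; >10 -> 3."""
    if not 0 <= blasts <= 100:
        raise ValueError(f"blasts must be in [0, 100] %, got {blasts}")
    if blasts <= 2:
        return 0.0
    if blasts < 5:
        return 1.0
    if blasts <= 10:
        return 2.0
    return 3.0


def score_hemoglobin(hgb: float) -> float:
    """Hemoglobin points: >=10 g/dL -> 0; 8-<10 -> 1; <8 -> 1.5."""
    if not hgb > 0:
        raise ValueError(f"hemoglobin must be > 0 g/dL, got {hgb}")
    if hgb >= 10:
        return 0.0
    if hgb >= 8:
        return 1.0
    return 1.5


def score_platelets(plt: float) -> float:
    """Platelet points: >=100 (10^9/L) -> 0; 50-<100 -> 0.5; <50 -> 1."""
    if plt < 0:
        raise ValueError(f"platelets must be >= 0, got {plt}")
    if plt >= 100:
        return 0.0
    if plt >= 50:
        return 0.5
    return 1.0


def score_anc(anc: float) -> float:
    """Absolute neutrophil count points: >=0.8 (10^9/L) -> 0; <0.8 -> 0.5."""
    if anc < 0:
        raise ValueError(f"ANC must be >= 0, got {anc}")
    return 0.0 if anc >= 0.8 else 0.5


def ipssr_category(total: float) -> str:
    """Risk category from the raw total: <=1.5 very low; >1.5-3 low;
    >3-4.5 intermediate; >4.5-6 high; >6 very high."""
    if total <= 1.5:
        return "very_low"
    if total <= 3:
        return "low"
    if total <= 4.5:
        return "intermediate"
    if total <= 6:
        return "high"
    return "very_high"


def ipssr_total(components: ClinicalComponents) -> IPSSRResult:
    """Score all five components and sum them into the IPSS-R total.

    The total lives on the half-point grid {0, 0.5, ..., 10}.  Downstream
    combined scoring uses this raw total, not the 1-5 category index.
    """
    p_cyto = float(components.cyto.points)
    p_blasts = score_blasts(components.blasts)
    p_hgb = score_hemoglobin(components.hemoglobin)
    p_plt = score_platelets(components.platelets)
    p_anc = score_anc(components.anc)
    total = p_cyto + p_blasts + p_hgb + p_plt + p_anc
    return IPSSRResult(
        points_cyto=p_cyto,
        points_blasts=p_blasts,
        points_hgb=p_hgb,
        points_plt=p_plt,
        points_anc=p_anc,
        total=total,
        category=ipssr_category(total),
    )
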