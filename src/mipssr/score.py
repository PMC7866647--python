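"""The MIPSS-R combined score: mutation points blended with the IPSS-R.

The score is a linear combination of the two component scores,

    MIPSS-R = 1.047 x mutation points + 0.641 x IPSS-R total,

where the weights are the multivariate Cox log-hazard coefficients of the
two scores and can be re-derived on any cohort (:func:`derive_weights`).
Patients are classified into five risk groups by quintiles of the score
distribution; the published groups are observed per-quintile score ranges

    very low 1.28-2.24, low 2.33-3.93, intermediate 4.02-4.34,
    high 4.57-5.30, very high 5.62-8.59,

and decision thresholds between adjacent groups are placed at the
midpoints of the inter-range gaps (2.285, 3.975, 4.455, 5.460), so the
classifier is total over the whole score line: anything below the lowest
range is very low, anything above the highest is very high.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import survival
from .ipssr import ClinicalComponents, ipssr_total
from .karyotype import classify_cytogenetics, cyto_from_label, parse_iscn
from .mutations import DEFAULT_PANEL, mutation_stratum, normalize_genes

__all__ = [
    "DEFAULT_BINS",
    "DEFAULT_WEIGHTS",
    "MIPSSR_CATEGORIES",
    "MIPSSRResult",
    "MIPSSRWeights",
    "MigrationTable",
    "QuintileBins",
    "classify_mipssr",
    "compare_stratifications",
    "derive_bins",
    "derive_weights",
    "mipssr_score",
    "round_half_up",
    "score_cohort",
]

MIPSSR_CATEGORIES = ("very_low", "low", "intermediate", "high", "very_high")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, for display of scores (1.285 -> 1.29).

    Floating noise is flushed at 6 decimals first so that grid values such
    as 0.3205 round on their decimal representation, not their binary one.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(round(float(x), 6))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MIPSSRWeights:
    """Per-point log-hazard weights for the two component scores."""

    coef_mut: float = 1.047
    coef_ipssr: float = 0.641

    def __post_init__(self) -> None:
        if not (np.isfinite(self.coef_mut) and np.isfinite(self.coef_ipssr)):
            raise ValueError("weights must be finite")


DEFAULT_WEIGHTS = MIPSSRWeights()


@dataclass(frozen=True)
class QuintileBins:
    """Observed (lo, hi) score ranges of the five quintile risk groups."""

    ranges: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.ranges) != 5:
            raise ValueError("exactly five quintile ranges are required")
        flat = [v for r in self.ranges for v in r]
        if any(lo > hi for lo, hi in self.ranges) or flat != sorted(flat):
            raise ValueError("ranges must be ordered and non-overlapping")

    @property
    def thresholds(self) -> tuple[float, float, float, float]:
        """Decision cut points: midpoints of the gaps between ranges."""
        return tuple(
            (self.ranges[k][1] + self.ranges[k + 1][0]) / 2.0 for k in range(4)
        )


DEFAULT_BINS = QuintileBins(
    ranges=((1.28, 2.24), (2.33, 3.93), (4.02, 4.34), (4.57, 5.30), (5.62, 8.59))
)


@dataclass(frozen=True)
class MIPSSRResult:
    score: float
    score_display: float
    category: str


def classify_mipssr(score: float, bins: QuintileBins = DEFAULT_BINS) -> str:
    """Five-level risk group for a score, classified at full precision."""
    if not np.isfinite(score):
        raise ValueError(f"score must be finite, got {score}")
    for category, t in zip(MIPSSR_CATEGORIES, bins.thresholds):
        if score <= t:
            return category
    return MIPSSR_CATEGORIES[-1]


def mipssr_score(
    mut_points: float,
    ipssr_total: float,
    weights: MIPSSRWeights = DEFAULT_WEIGHTS,
    bins: QuintileBins = DEFAULT_BINS,
) -> MIPSSRResult:
    """Combine mutation points and the raw IPSS-R total into the score.

    ``score_display`` is the two-decimal half-up rounding used in reports;
    classification always uses the full-precision score.
    """
    score = weights.coef_mut * float(mut_points) + weights.coef_ipssr * float(ipssr_total)
    return MIPSSRResult(
        score=score,
        score_display=round_half_up(score, 2),
        category=classify_mipssr(score, bins),
    )


def derive_weights(
    cohort: pd.DataFrame,
    duration_col: str = "os_months",
    event_col: str = "event",
    covariates: tuple[str, str] = ("mut_points", "ipssr_total"),
) -> MIPSSRWeights:
    """Re-derive the two weights as multivariate Cox coefficients.

    Fits overall survival on the mutation points and the raw IPSS-R total
    jointly; the log hazard ratios become the combination weights.
    """
    fit = survival.cox_fit(cohort, duration_col, event_col, list(covariates))
    return MIPSSRWeights(
        coef_mut=float(fit.coef[covariates[0]]),
        coef_ipssr=float(fit.coef[covariates[1]]),
    )


def derive_bins(scores) -> QuintileBins:
    """Quintile-bin a score distribution.

    Splits at the 20/40/60/80th percentiles and reports each group as the
    (min, max) of its observed scores, mirroring how the published ranges
    are stated.  Requires at least five distinct score values; the five
    groups must be separated by strict gaps (guaranteed for continuous
    scores) so that classification round-trips group membership exactly.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 5 or np.unique(s).size < 5:
        raise ValueError("need at least five distinct scores to form quintiles")
    qs = np.quantile(s, [0.2, 0.4, 0.6, 0.8])
    group = np.searchsorted(qs, s, side="left")  # score <= q_k -> group k
    ranges = []
    for g in range(5):
        member = s[group == g]
        if member.size == 0:
            raise ValueError("a quintile group is empty; scores too discrete")
        ranges.append((float(member.min()), float(member.max())))
    for k in range(4):
        if ranges[k][1] >= ranges[k + 1][0]:
            raise ValueError(
                "tied scores straddle a quintile boundary; groups overlap"
            )
    return QuintileBins(ranges=tuple(ranges))


@dataclass(frozen=True)
class MigrationTable:
    """Risk migration between two five-level stratifications."""

    n: int
    decreased: int
    unchanged: int
    elevated: int
    crosstab: pd.DataFrame

    @property
    def pct_decreased(self) -> float:
        return round_half_up(100.0 * self.decreased / self.n, 2)

    @property
    def pct_elevated(self) -> float:
        return round_half_up(100.0 * self.elevated / self.n, 2)

    @property
    def pct_changed(self) -> float:
        return round_half_up(100.0 * (self.decreased + self.elevated) / self.n, 2)


def compare_stratifications(
    levels_a, levels_b, categories: tuple[str, ...] = MIPSSR_CATEGORIES
) -> MigrationTable:
    """Ordinal comparison of two per-patient risk assignments.

    ``levels_a`` is the reference system (e.g. IPSS-R category) and
    ``levels_b`` the new one (e.g. MIPSS-R category), both on the same
    ordered five-level scale.  Counts patients whose risk decreased,
    stayed, or rose, and tabulates the full 5x5 cross table.
    """
    index = {c: i for i, c in enumerate(categories)}
    a = list(levels_a)
    b = list(levels_b)
    if len(a) != len(b) or not a:
        raise ValueError("the two stratifications must be equal-length, non-empty")
    for lab in (*a, *b):
        if lab not in index:
            raise ValueError(f"unmapped category label {lab!r}")
    ia = np.array([index[x] for x in a])
    ib = np.array([index[x] for x in b])
    cross = pd.crosstab(
        pd.Categorical(a, categories=categories),
        pd.Categorical(b, categories=categories),
        dropna=False,
    )
    cross.index.name, cross.columns.name = "system_a", "system_b"
    return MigrationTable(
        n=len(a),
        decreased=int((ib < ia).sum()),
        unchanged=int((ib == ia).sum()),
        elevated=int((ib > ia).sum()),
        crosstab=cross,
    )


def score_cohort(
    cohort: pd.DataFrame,
    weights: MIPSSRWeights = DEFAULT_WEIGHTS,
    bins: QuintileBins = DEFAULT_BINS,
    panel=DEFAULT_PANEL,
) -> pd.DataFrame:
    """Score every patient in a cohort frame end to end.

    Expects the canonical cohort columns (``hgb_gdl``, ``plt_1e9l``,
    ``anc_1e9l``, ``blasts_pct``, ``karyotype`` or ``cyto_category``,
    ``mutations``) and appends ``ipssr_total``, ``ipssr_category``,
    ``mut_points``, ``mut_stratum``, ``mipssr_score`` (two decimals) and
    ``mipssr_category``.
    """
    out = cohort.copy()
    totals, ipssr_cats, mpoints, strata, scores, cats = [], [], [], [], [], []
    for _, row in cohort.iterrows():
        if "cyto_category" in cohort.columns and pd.notna(row.get("cyto_category")):
            cyto = cyto_from_label(row["cyto_category"])
        elif "karyotype" in cohort.columns and pd.notna(row.get("karyotype")):
            cyto = classify_cytogenetics(parse_iscn(row["karyotype"]))
        else:
            raise ValueError(f"row {row.get('id', '?')}: no karyotype or cyto_category")
        comp = ClinicalComponents(
            hemoglobin=float(row["hgb_gdl"]),
            platelets=float(row["plt_1e9l"]),
            anc=float(row["anc_1e9l"]),
            blasts=float(row["blasts_pct"]),
            cyto=cyto,
        )
        ipssr = ipssr_total(comp)
        mscore = mutation_stratum(normalize_genes(row.get("mutations", ""), panel))
        res = mipssr_score(mscore.points, ipssr.total, weights, bins)
        totals.append(ipssr.total)
        ipssr_cats.append(ipssr.category)
        mpoints.append(mscore.points)
        strata.append(mscore.stratum)
        scores.append(res.score_display)
        cats.append(res.category)
    out["ipssr_total"] = totals
    out["ipssr_category"] = ipssr_cats
    out["mut_points"] = mpoints
    out["mut_stratum"] = strata
    out["mipssr_score"] = scores
    out["mipssr_category"] = cats
    return out
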