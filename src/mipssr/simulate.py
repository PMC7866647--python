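"""Synthetic MDS cohorts for testing the scoring and validation pipeline.

The generator emulates the statistical shape of a real-world MDS cohort:
blood counts and blast percentages drawn from skewed distributions with
realistic medians and ranges (hemoglobin ~9 g/dL, platelets ~80 x 10^9/L,
ANC ~1.4 x 10^9/L, blasts mostly low with a tail to 28%), per-gene
mutation prevalences led by ASXL1 / TET2 / TP53 / SRSF2 / SF3B1, a
five-way cytogenetic-category mix with roughly 9% complex karyotypes, and
overall survival generated from a Weibull proportional-hazards model whose
log hazard is the weighted sum of the mutation points and the IPSS-R total
— i.e. exactly the structure the combined score assumes.  Right censoring
is administrative: a uniform censoring time over a follow-up window.

Components are sampled independently of one another; the cohorts are
faithful to the marginal distributions, not to clinical correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ipssr import ClinicalComponents, ipssr_total
from .karyotype import CYTO_LEVELS, CytoCategory
from .mutations import DEFAULT_PANEL, MutationProfile, mutation_stratum

__all__ = [
    "DEFAULT_CYTO_PROBS",
    "DEFAULT_GENE_PREVALENCE",
    "SimConfig",
    "TRUTH_COLUMNS",
    "prevalence_check",
    "simulate_cohort",
]

#: Per-gene mutation prevalences: the five most common MDS genes at their
#: observed cohort frequencies, the rest of the default panel at a low
#: background rate.
DEFAULT_GENE_PREVALENCE: dict[str, float] = {
    **{g: 0.04 for g in sorted(DEFAULT_PANEL)},
    "ASXL1": 0.315,
    "TET2": 0.278,
    "TP53": 0.185,
    "SRSF2": 0.148,
    "SF3B1": 0.148,
}

DEFAULT_CYTO_PROBS: dict[str, float] = {
    "very_good": 0.02,
    "good": 0.66,
    "intermediate": 0.15,
    "poor": 0.08,
    "very_poor": 0.09,
}

#: Latent-truth columns, excluded from the standard cohort writer.
TRUTH_COLUMNS = (
    "mut_points",
    "ipssr_total",
    "true_linear_predictor",
    "uncensored_months",
)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generator settings; defaults mirror a real-world MDS cohort.

    Survival: Weibull baseline with hazard multiplier
    ``exp(coef_mut * mut_points + coef_ipssr * ipssr_total - centering)``,
    where the centering constant anchors the time scale at a typical
    patient so that ``scale_months`` is interpretable as that patient's
    characteristic survival time.  Censoring times are uniform on
    ``(0, censor_window_months)``.
    """

    n: int = 500
    seed: int = 0
    gene_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_PREVALENCE)
    )
    cyto_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CYTO_PROBS)
    )
    # component distributions (units: g/dL, 10^9/L, 10^9/L, %)
    hgb_mean: float = 9.2
    hgb_sd: float = 2.4
    hgb_range: tuple[float, float] = (3.3, 15.2)
    plt_median: float = 81.5
    plt_log_sigma: float = 1.0
    plt_range: tuple[float, float] = (2.0, 987.0)
    anc_median: float = 1.4
    anc_log_sigma: float = 0.9
    anc_range: tuple[float, float] = (0.07, 28.0)
    blasts_scale: float = 3.0
    blasts_max: float = 28.0
    age_mean: float = 70.0
    age_sd: float = 12.0
    age_range: tuple[float, float] = (24.0, 91.0)
    male_frac: float = 0.69
    # survival model
    coef_mut: float = 1.047
    coef_ipssr: float = 0.641
    weibull_shape: float = 1.0
    scale_months: float = 30.0
    centering: float = 1.047 * 2 + 0.641 * 3.5  # a typical patient's log hazard
    censor_window_months: float = 60.0

    def validate(self) -> None:
        problems = []
        if self.n < 1:
            problems.append(f"n must be >= 1, got {self.n}")
        for gene, p in self.gene_prevalence.items():
            if not 0 <= p <= 1:
                problems.append(f"prevalence of {gene} must be in [0, 1], got {p}")
        if set(self.cyto_probs) != set(CYTO_LEVELS):
            problems.append(f"cyto_probs must cover exactly {CYTO_LEVELS}")
        elif not np.isclose(sum(self.cyto_probs.values()), 1.0):
            problems.append("cyto_probs must sum to 1")
        if any(p < 0 for p in self.cyto_probs.values()):
            problems.append("cyto_probs must be nonnegative")
        if self.weibull_shape <= 0 or self.scale_months <= 0:
            problems.append("weibull_shape and scale_months must be > 0")
        if self.censor_window_months <= 0:
            problems.append("censor_window_months must be > 0")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _truncated(draw, lo: float, hi: float) -> np.ndarray:
    return np.clip(draw, lo, hi)


def simulate_cohort(config: SimConfig | None = None, **overrides) -> pd.DataFrame:
    """Generate a synthetic cohort; byte-identical for identical configs.

    Returns one row per patient with the canonical input columns plus the
    latent truth (:data:`TRUTH_COLUMNS`): the computed component scores,
    the true linear predictor and the uncensored event time.
    """
    config = (config or SimConfig()).with_(**overrides) if overrides else (
        config or SimConfig()
    )
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    hgb = _truncated(rng.normal(config.hgb_mean, config.hgb_sd, n), *config.hgb_range)
    plt = _truncated(
        np.exp(rng.normal(np.log(config.plt_median), config.plt_log_sigma, n)),
        *config.plt_range,
    )
    anc = _truncated(
        np.exp(rng.normal(np.log(config.anc_median), config.anc_log_sigma, n)),
        *config.anc_range,
    )
    blasts = _truncated(rng.exponential(config.blasts_scale, n), 0.0, config.blasts_max)
    age = _truncated(rng.normal(config.age_mean, config.age_sd, n), *config.age_range)
    sex = np.where(rng.random(n) < config.male_frac, "M", "F")

    levels = list(config.cyto_probs)
    cyto = rng.choice(levels, size=n, p=[config.cyto_probs[l] for l in levels])

    genes = sorted(config.gene_prevalence)
    prev = np.array([config.gene_prevalence[g] for g in genes])
    hit = rng.random((n, len(genes))) < prev
    mutations = [";".join(g for g, h in zip(genes, row) if h) for row in hit]

    mut_points = np.empty(n)
    ipssr_tot = np.empty(n)
    for i in range(n):
        profile = MutationProfile(
            genes=frozenset(mutations[i].split(";")) - {""}, panel=None
        )
        mut_points[i] = mutation_stratum(profile).points
        comp = ClinicalComponents(
            hemoglobin=float(np.round(hgb[i], 1)),
            platelets=float(np.round(plt[i], 0)),
            anc=float(np.round(anc[i], 2)),
            blasts=float(np.round(blasts[i], 1)),
            cyto=CytoCategory(str(cyto[i])),
        )
        ipssr_tot[i] = ipssr_total(comp).total

    eta = config.coef_mut * mut_points + config.coef_ipssr * ipssr_tot
    u = rng.random(n)
    event_time = config.scale_months * (
        -np.log(u) / np.exp(eta - config.centering)
    ) ** (1.0 / config.weibull_shape)
    censor_time = rng.uniform(0.0, config.censor_window_months, n)
    os_months = np.maximum(np.minimum(event_time, censor_time), 1e-6)
    event = (event_time <= censor_time).astype(int)

    return pd.DataFrame(
        {
            "id": [f"P{i + 1:05d}" for i in range(n)],
            "age": np.round(age, 0).astype(int),
            "sex": sex,
            "hgb_gdl": np.round(hgb, 1),
            "plt_1e9l": np.round(plt, 0),
            "anc_1e9l": np.round(anc, 2),
            "blasts_pct": np.round(blasts, 1),
            "cyto_category": cyto,
            "mutations": mutations,
            "os_months": os_months,
            "event": event,
            "mut_points": mut_points.astype(int),
            "ipssr_total": ipssr_tot,
            "true_linear_predictor": eta,
            "uncensored_months": event_time,
        }
    )


def prevalence_check(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Observed vs. configured per-gene mutation frequencies.

    The 99% binomial bounds use the normal approximation around the
    configured prevalence; ``within`` flags genes whose observed frequency
    falls inside them.
    """
    n = len(cohort)
    gene_sets = [set(str(m).split(";")) - {""} for m in cohort["mutations"]]
    rows = []
    for gene, p in sorted(config.gene_prevalence.items()):
        obs = sum(gene in gs for gs in gene_sets) / n
        half = 2.5758 * np.sqrt(p * (1 - p) / n)
        lo, hi = max(0.0, p - half), min(1.0, p + half)
        rows.append(
            {
                "gene": gene,
                "expected": p,
                "observed": obs,
                "lo99": lo,
                "hi99": hi,
                "within": lo <= obs <= hi,
            }
        )
    return pd.DataFrame(rows)
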