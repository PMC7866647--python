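"""Mutation risk stratification: 0-3 points from the mutated-gene count.

The rule is deliberately simple so that it can be applied to any panel
result without per-gene hazard estimates: patients with no pathogenic
mutation, or with SF3B1 as their only mutation, are low risk (0 points);
one mutated gene other than SF3B1 is intermediate-1 (1 point); two to four
mutated genes are intermediate-2 (2 points); five or more are high risk
(3 points).  SF3B1 is the single favorable gene — its privilege applies
only when it is the sole mutation; when co-mutated it counts toward the
total like any other gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PANEL",
    "MUTATION_STRATA",
    "MutationProfile",
    "MutationScore",
    "load_panel",
    "mutation_stratum",
    "normalize_genes",
    "stratum_from_count",
]

MUTATION_STRATA = ("low", "intermediate_1", "intermediate_2", "high")
_STRATUM_POINTS = {s: p for p, s in enumerate(MUTATION_STRATA)}

#: Default 31-gene targeted myeloid panel.  This is a synthetic stand-in,
#: a representative roster of genes recurrently mutated in MDS (epigenetic
#: regulators, spliceosome, cohesin, transcription factors, signaling);
#: assays differ between laboratories, so the panel is configurable via
#: :func:`load_panel`.
DEFAULT_PANEL = frozenset(
    {
        "ASXL1", "BCOR", "BCORL1", "CBL", "CEBPA", "CSF3R", "DNMT3A",
        "ETV6", "EZH2", "FLT3", "GATA2", "IDH1", "IDH2", "JAK2", "KIT",
        "KRAS", "NF1", "NPM1", "NRAS", "PHF6", "PTPN11", "RUNX1",
        "SETBP1", "SF3B1", "SRSF2", "STAG2", "TET2", "TP53", "U2AF1",
        "WT1", "ZRSR2",
    }
)


@dataclass(frozen=True)
class MutationProfile:
    """The set of genes carrying >=1 pathogenic variant in one patient."""

    genes: frozenset[str]
    panel: frozenset[str] | None = DEFAULT_PANEL
    dropped: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.panel is not None and not self.genes <= self.panel:
            off = sorted(self.genes - self.panel)
            raise ValueError(f"genes outside the panel after filtering: {off}")


@dataclass(frozen=True)
class MutationScore:
    stratum: str

    def __post_init__(self) -> None:
        if self.stratum not in _STRATUM_POINTS:
            raise ValueError(
                f"unknown stratum {self.stratum!r}; expected one of {MUTATION_STRATA}"
            )

    @property
    def points(self) -> int:
        return _STRATUM_POINTS[self.stratum]


def normalize_genes(
    raw: str | None,
    panel: frozenset[str] | None = DEFAULT_PANEL,
    *,
    delimiter: str = ";",
) -> MutationProfile:
    """Turn a delimited gene-symbol string into a :class:`MutationProfile`.

    Symbols are uppercased, stripped and deduplicated; an empty string (or
    None/NaN) means no mutations.  Commas are accepted in place of the
    canonical semicolon, with a warning.  Genes absent from ``panel`` are
    dropped with a logged warning and recorded in ``profile.dropped``;
    pass ``panel=None`` to keep every symbol.
    """
    if raw is None or (isinstance(raw, float) and raw != raw):  # NaN-safe
        raw = ""
    text = str(raw).strip()
    if "," in text and delimiter not in text:
        logger.warning("gene list %r uses ',' as delimiter; accepting it", text)
        text = text.replace(",", delimiter)
    symbols = {s.strip().upper() for s in text.split(delimiter) if s.strip()}
    if panel is None:
        return MutationProfile(genes=frozenset(symbols), panel=None)
    dropped = tuple(sorted(symbols - panel))
    if dropped:
        logger.warning("dropping genes not on the panel: %s", ", ".join(dropped))
    return MutationProfile(genes=frozenset(symbols & panel), panel=panel, dropped=dropped)


def stratum_from_count(n_mutated: int, sf3b1_only: bool) -> MutationScore:
    """Map a distinct-mutated-gene count to the four-level stratum.

    ``sf3b1_only`` flags the one privileged case: a single mutation that is
    SF3B1.  0 mutations or SF3B1-only -> low; 1 -> intermediate-1;
    2-4 -> intermediate-2; >=5 -> high.
    """
    if n_mutated < 0:
        raise ValueError("mutation count cannot be negative")
    if sf3b1_only and n_mutated != 1:
        raise ValueError("sf3b1_only requires exactly one mutated gene")
    if n_mutated == 0 or sf3b1_only:
        return MutationScore("low")
    if n_mutated == 1:
        return MutationScore("intermediate_1")
    if n_mutated <= 4:
        return MutationScore("intermediate_2")
    return MutationScore("high")


def mutation_stratum(
    profile: MutationProfile, *, n_mutations: int | None = None
) -> MutationScore:
    """Stratify a mutation profile into low / int-1 / int-2 / high.

    By default the count is the number of distinct mutated genes.  Callers
    tracking multiple variants per gene may pass ``n_mutations`` to count
    variants instead; the SF3B1-only privilege then requires that all
    variants fall in SF3B1.
    """
    count = len(profile.genes) if n_mutations is None else n_mutations
    sf3b1_only = profile.genes == {"SF3B1"} and count == 1
    return stratum_from_count(count, sf3b1_only)


def load_panel(path: str) -> frozenset[str]:
    """Read a panel file: one gene symbol per line, ``#`` comments allowed."""
    symbols = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip().upper()
            if sym:
                symbols.add(sym)
    if not symbols:
        raise ValueError(f"panel file {path!r} contains no gene symbols")
    return frozenset(symbols)
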