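"""Cohort table I/O and model serialization.

The canonical cohort format is a UTF-8 TSV with a header row and columns
``id``, ``hgb_gdl``, ``plt_1e9l``, ``anc_1e9l``, ``blasts_pct``,
``karyotype`` *or* ``cyto_category``, ``mutations`` (semicolon-delimited
gene symbols, empty = none), ``os_months`` and ``event`` (0/1); ``age``
and ``sex`` are optional.  CSV is accepted on read.  Row-level problems
are collected with their line numbers rather than failing at the first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .score import MIPSSRWeights, QuintileBins

__all__ = [
    "CohortSchemaError",
    "CohortValidationError",
    "load_model",
    "read_cohort",
    "save_model",
    "write_cohort",
    "write_scored",
]

MANDATORY = ("id", "hgb_gdl", "plt_1e9l", "anc_1e9l", "blasts_pct", "os_months", "event")
NUMERIC = ("hgb_gdl", "plt_1e9l", "anc_1e9l", "blasts_pct", "os_months")

SCORED_COLUMNS = (
    "ipssr_total",
    "ipssr_category",
    "mut_points",
    "mut_stratum",
    "mipssr_score",
    "mipssr_category",
)


class CohortSchemaError(ValueError):
    """The file is missing mandatory columns."""


@dataclass
class CohortValidationError(ValueError):
    """One or more rows failed validation; ``errors`` holds (line, message)."""

    errors: list[tuple[int, str]]

    def __str__(self) -> str:
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in self.errors[:10])
        extra = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        return f"{len(self.errors)} invalid row(s): {lines}{extra}"


def _sep_for(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if str(path).lower().endswith(".csv") else "tsv"
    return {"tsv": "\t", "csv": ","}[fmt]


def read_cohort(path: str, fmt: str | None = None, *, strict: bool = True):
    """Read and validate a cohort table.

    With ``strict=True`` (default) any row error raises
    :class:`CohortValidationError` listing every offending line.  With
    ``strict=False`` invalid rows are dropped and a
    ``(frame, errors)`` tuple is returned so callers can report them.
    """
    df = pd.read_csv(path, sep=_sep_for(path, fmt), dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY if c not in df.columns]
    if "karyotype" not in df.columns and "cyto_category" not in df.columns:
        missing.append("karyotype|cyto_category")
    if "mutations" not in df.columns:
        missing.append("mutations")
    if missing:
        raise CohortSchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    errors: list[tuple[int, str]] = []
    parsed = df.copy()
    for col in NUMERIC:
        vals = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        bad = vals.isna()
        for idx in df.index[bad]:
            errors.append((idx + 2, f"column {col!r}: cannot parse {df.at[idx, col]!r}"))
        parsed[col] = vals
    ev = pd.to_numeric(df["event"].replace("", np.nan), errors="coerce")
    bad_ev = ~ev.isin([0, 1])
    for idx in df.index[bad_ev]:
        errors.append((idx + 2, f"column 'event': expected 0 or 1, got {df.at[idx, 'event']!r}"))
    parsed["event"] = ev
    dup = df["id"].duplicated(keep=False)
    for idx in df.index[dup]:
        errors.append((idx + 2, f"duplicate id {df.at[idx, 'id']!r}"))

    if errors:
        errors.sort()
        if strict:
            raise CohortValidationError(errors)
        bad_lines = {ln for ln, _ in errors}
        keep = [i for i in parsed.index if i + 2 not in bad_lines]
        parsed = parsed.loc[keep].reset_index(drop=True)
        parsed["event"] = parsed["event"].astype(int)
        return parsed, errors
    parsed["event"] = parsed["event"].astype(int)
    return parsed if strict else (parsed, [])


def write_cohort(df: pd.DataFrame, path: str, *, with_truth: bool = False) -> None:
    """Write a cohort TSV; latent-truth columns are dropped unless asked for."""
    from .simulate import TRUTH_COLUMNS

    out = df if with_truth else df.drop(
        columns=[c for c in TRUTH_COLUMNS if c in df.columns]
    )
    out.to_csv(path, sep="\t", index=False)


def write_scored(df: pd.DataFrame, path: str) -> None:
    """Write a scored cohort TSV.

    Input columns keep their order; the appended score columns follow in a
    stable order, with ``mipssr_score`` rendered at two decimals so the
    file round-trips through :func:`read_cohort` unchanged.
    """
    missing = [c for c in SCORED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"not a scored cohort; missing column(s): {missing}")
    ordered = [c for c in df.columns if c not in SCORED_COLUMNS] + list(SCORED_COLUMNS)
    out = df[ordered].copy()
    out["mipssr_score"] = out["mipssr_score"].map(lambda v: f"{float(v):.2f}")
    out.to_csv(path, sep="\t", index=False)


def save_model(weights: MIPSSRWeights, bins: QuintileBins, path: str) -> None:
    """Serialize weights + quintile bins to JSON (round-trip stable)."""
    payload = {
        "coef_mut": weights.coef_mut,
        "coef_ipssr": weights.coef_ipssr,
        "bins": [list(r) for r in bins.ranges],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_model(path: str) -> tuple[MIPSSRWeights, QuintileBins]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    weights = MIPSSRWeights(
        coef_mut=float(payload["coef_mut"]), coef_ipssr=float(payload["coef_ipssr"])
    )
    bins = QuintileBins(ranges=tuple(tuple(map(float, r)) for r in payload["bins"]))
    return weights, bins
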