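"""ISCN karyotype parsing and IPSS-R cytogenetic risk classification.

Karyotype strings are parsed into normalized aberration tokens
(``"-7"``, ``"del(5q)"``, ``"+8"``, ``"i(17q)"``, ...) and mapped onto the
five-level cytogenetic risk scale used by the revised International
Prognostic Scoring System (IPSS-R): very good, good, intermediate, poor,
very poor, worth 0-4 points.

Only the subset of ISCN needed for risk classification is supported:
comma-separated clone descriptions, an optional modal chromosome number and
sex-chromosome field, numeric/structural aberrations, and mosaic clones
separated by ``/``.  Band-level detail beyond the chromosome arm is parsed
but discarded.  Composite karyotypes, ``idem`` shorthand and uncertainty
qualifiers are out of scope and raise :class:`KaryotypeParseError`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "CYTO_LEVELS",
    "CYTO_POINTS",
    "CytoCategory",
    "KaryotypeParseError",
    "KaryotypeReport",
    "classify_cytogenetics",
    "cyto_from_label",
    "parse_iscn",
]

#: Cytogenetic risk levels, best to worst, and their IPSS-R points.
CYTO_LEVELS = ("very_good", "good", "intermediate", "poor", "very_poor")
CYTO_POINTS = {level: points for points, level in enumerate(CYTO_LEVELS)}


class KaryotypeParseError(ValueError):
    """Raised when an ISCN string contains a token that cannot be parsed."""


@dataclass(frozen=True)
class CytoCategory:
    """One of the five IPSS-R cytogenetic risk groups."""

    level: str

    def __post_init__(self) -> None:
        if self.level not in CYTO_POINTS:
            raise ValueError(
                f"unknown cytogenetic level {self.level!r}; "
                f"expected one of {CYTO_LEVELS}"
            )

    @property
    def points(self) -> int:
        return CYTO_POINTS[self.level]


@dataclass(frozen=True)
class KaryotypeReport:
    """Parsed karyotype: normalized aberration tokens per clone.

    ``abnormalities`` holds the tokens of the risk-dominant clone (for a
    single-clone karyotype, simply that clone); ``clones`` keeps every clone
    so mosaic karyotypes can be classified conservatively on the worst one.
    A karyotype is *complex* when it carries three or more abnormalities.
    """

    raw: str
    abnormalities: tuple[str, ...]
    clones: tuple[tuple[str, ...], ...] = field(default=())

    @property
    def n_abnormalities(self) -> int:
        return len(self.abnormalities)

    @property
    def is_complex(self) -> bool:
        return self.n_abnormalities >= 3


_MODAL_RE = re.compile(r"^\d{1,3}(?:[-~]\d{1,3})?$")
_SEX_RE = re.compile(r"^[XY]{1,4}$")
_CELLCOUNT_RE = re.compile(r"\[\d+\]\s*$")

_GAIN_LOSS_RE = re.compile(r"^([+-])(\d{1,2}|X|Y)$")
_DEL_BAND_RE = re.compile(r"^del\((\d{1,2}|X|Y)\)\(([pq])[\w.;]*\)$")
_DEL_SHORT_RE = re.compile(r"^del\((\d{1,2}|X|Y)([pq])\)$")
_ARM_MINUS_RE = re.compile(r"^(\d{1,2}|X|Y)([pq])-$")  # clinical shorthand "5q-"
_ISO_BAND_RE = re.compile(r"^i\((\d{1,2}|X|Y)\)\(([pq])[\w.]*\)$")
_ISO_SHORT_RE = re.compile(r"^i\((\d{1,2}|X|Y)([pq])\)$")
_INV_RE = re.compile(r"^inv\((\d{1,2}|X|Y)\)(?:\([\w.;]*\))?$")
_TRANSLOC_RE = re.compile(r"^t\(([\dXY;]+)\)(?:\(([\w.;]*)\))?$")
_OTHER_RE = re.compile(
    r"^(?:add|dup|der|ins|idic|dic|trp|r|hsr)\([\dXY;]+\)(?:\([\w.;]*\))*$"
)
_MARKER_RE = re.compile(r"^\+?\d*mar\d*$")


def _normalize_token(token: str) -> str:
    """Map one ISCN aberration token to its normalized form."""
    tok = token.strip()
    if not tok:
        raise KaryotypeParseError("empty aberration token")

    if m := _GAIN_LOSS_RE.match(tok):
        return f"{m.group(1)}{m.group(2)}"
    if m := _DEL_BAND_RE.match(tok) or _DEL_SHORT_RE.match(tok):
        return f"del({m.group(1)}{m.group(2)})"
    if m := _ARM_MINUS_RE.match(tok):
        return f"del({m.group(1)}{m.group(2)})"
    if m := _ISO_BAND_RE.match(tok) or _ISO_SHORT_RE.match(tok):
        return f"i({m.group(1)}{m.group(2)})"
    if m := _INV_RE.match(tok):
        return f"inv({m.group(1)})"
    if m := _TRANSLOC_RE.match(tok):
        chroms = m.group(1).split(";")
        bands = (m.group(2) or "").split(";")
        # 3q translocations form their own IPSS-R risk entity
        for i, c in enumerate(chroms):
            if c == "3" and i < len(bands) and bands[i].startswith("q"):
                return "t(3q)"
        return f"t({';'.join(chroms)})"
    if _MARKER_RE.match(tok):
        return "+mar"
    if _OTHER_RE.match(tok):
        return tok
    raise KaryotypeParseError(f"unparseable ISCN token: {token!r}")


def _parse_clone(clone: str) -> tuple[str, ...]:
    fields = [f.strip() for f in clone.split(",")]
    idx = 0
    if fields and _MODAL_RE.match(fields[0]):
        idx = 1
    if idx < len(fields) and _SEX_RE.match(fields[idx]):
        idx += 1
    if idx == 0:
        raise KaryotypeParseError(
            f"clone {clone!r} lacks a modal number / sex-chromosome prefix"
        )
    return tuple(_normalize_token(tok) for tok in fields[idx:] if tok)


def parse_iscn(karyotype: str) -> KaryotypeReport:
    """Parse an ISCN clone description into a :class:`KaryotypeReport`.

    The sex-chromosome constitution and modal number are not counted as
    abnormalities; a lost Y written as an explicit ``-Y`` token *is*
    counted.  Mosaic karyotypes (clones separated by ``/``) are parsed
    clone by clone and the report's top-level ``abnormalities`` refer to
    the clone with the worst cytogenetic risk.
    """
    if not isinstance(karyotype, str) or not karyotype.strip():
        raise KaryotypeParseError("karyotype must be a non-empty string")
    text = _CELLCOUNT_RE.sub("", karyotype.strip())
    clone_texts = [_CELLCOUNT_RE.sub("", c).strip() for c in text.split("/")]
    clones = tuple(_parse_clone(c) for c in clone_texts if c)
    if not clones:
        raise KaryotypeParseError(f"no clones found in {karyotype!r}")
    worst = max(clones, key=lambda toks: (_classify_clone(toks).points, len(toks)))
    return KaryotypeReport(raw=karyotype, abnormalities=worst, clones=clones)


# IPSS-R cytogenetic table: single-abnormality lookups.
_VERY_GOOD_SINGLE = {"-Y", "del(11q)"}
_GOOD_SINGLE = {"del(5q)", "del(12p)", "del(20q)"}
_INTERMEDIATE_SINGLE = {"del(7q)", "+8", "+19", "i(17q)"}
_POOR_SINGLE = {"-7", "inv(3)", "t(3q)", "del(3q)"}


def _classify_clone(tokens: tuple[str, ...]) -> CytoCategory:
    n = len(tokens)
    if n > 3:
        return CytoCategory("very_poor")
    if n == 3:
        return CytoCategory("poor")
    if n == 0:
        return CytoCategory("good")
    if n == 1:
        tok = tokens[0]
        if tok in _VERY_GOOD_SINGLE:
            return CytoCategory("very_good")
        if tok in _GOOD_SINGLE:
            return CytoCategory("good")
        if tok in _POOR_SINGLE:
            return CytoCategory("poor")
        # del(7q)/+8/+19/i(17q) and any other single abnormality
        return CytoCategory("intermediate")
    # n == 2; chromosome-7 loss dominates the double-including-del(5q) rule
    toks = set(tokens)
    if toks & {"-7", "del(7q)"}:
        return CytoCategory("poor")
    if "del(5q)" in toks:
        return CytoCategory("good")
    return CytoCategory("intermediate")


def classify_cytogenetics(report: KaryotypeReport) -> CytoCategory:
    """Assign the IPSS-R cytogenetic risk group for a parsed karyotype.

    The five-group rule: very good = isolated -Y or del(11q); good = normal,
    isolated del(5q)/del(12p)/del(20q), or any double including del(5q);
    intermediate = isolated del(7q)/+8/+19/i(17q) and any other single or
    double; poor = isolated -7 or 3q aberration, double including -7 or
    del(7q), or exactly three abnormalities; very poor = more than three
    abnormalities.  Mosaic karyotypes take the worst clone.
    """
    return max(
        (_classify_clone(toks) for toks in report.clones or (report.abnormalities,)),
        key=lambda c: c.points,
    )


def cyto_from_label(label: str) -> CytoCategory:
    """Build a :class:`CytoCategory` from a precomputed label column.

    Accepts ``very_good``/``good``/... case-insensitively, with spaces or
    hyphens in place of underscores (``"Very good"`` works).
    """
    norm = str(label).strip().lower().replace("-", "_").replace(" ", "_")
    return CytoCategory(norm)
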