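"""Absolute protein quantification from iBAQ intensities.

iBAQ intensities (summed precursor intensities divided by the number of
theoretically observable peptides) are roughly proportional to molar
protein amounts.  The workflow here: (i) normalize every sample on the
summed iBAQ of a small reference set of stable proteins, (ii) anchor the
normalized scale to an absolute amount known for one protein from
immunoblotting (PsaC, mean 104 fmol/uL), (iii) convert to molecules per
cell, and (iv) combine subunit copy numbers into protein-complex copy
numbers using database stoichiometries.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .params import AVOGADRO

#: reference proteins used for between-sample iBAQ normalization
#: (small SD, similar intensity range, extreme-condition ratio close to 1)
DEFAULT_REFERENCE_PROTEINS = ("Q55806", "P72587", "P73505", "Q59978")

MOLECULES_PER_FMOL = AVOGADRO * 1e-15


@dataclass(frozen=True)
class CalibrationSpec:
    """Reference set + anchor for absolute iBAQ calibration.

    ``anchor_amount`` is the known absolute amount of the anchor protein
    in the digested extract (fmol/uL); ``cells_per_volume`` the cell
    concentration of that extract (cells/uL), required to express copies
    per cell.
    """

    anchor_id: str
    cells_per_volume: float
    anchor_amount: float = 104.0
    reference_ids: tuple[str, ...] = DEFAULT_REFERENCE_PROTEINS

    def __post_init__(self) -> None:
        if not self.reference_ids:
            raise ValueError("reference_ids must be nonempty")
        if self.anchor_amount <= 0:
            raise ValueError("anchor_amount must be > 0")
        if self.cells_per_volume <= 0:
            raise ValueError("cells_per_volume must be > 0")


def normalize_ibaq(ibaq: pd.DataFrame,
                   spec: CalibrationSpec) -> pd.DataFrame:
    """Divide each sample by its summed reference-protein iBAQ.

    After normalization the reference sum is exactly 1 in every sample;
    the result is invariant to any per-sample intensity scaling.
    """
    missing = [r for r in spec.reference_ids if r not in ibaq.index]
    if missing:
        raise KeyError(f"reference proteins absent from matrix: {missing}")
    ref = ibaq.loc[list(spec.reference_ids)]
    bad = ref.columns[ref.isna().any(axis=0) | (ref <= 0).any(axis=0)]
    if len(bad):
        raise ValueError(
            "reference proteins missing or non-positive in samples: "
            f"{list(bad)}")
    return ibaq.div(ref.sum(axis=0), axis=1)


def calibrate_absolute(normalized: pd.DataFrame,
                       spec: CalibrationSpec) -> pd.DataFrame:
    """Convert normalized iBAQ to molecules per cell via the anchor protein.

    One global factor maps the anchor's grand-mean normalized intensity to
    ``anchor_amount`` (fmol/uL); fmol/uL become molecules per cell through
    Avogadro's number and ``cells_per_volume``.  Linear in
    ``anchor_amount`` and inverse-linear in ``cells_per_volume``.
    """
    if spec.anchor_id not in normalized.index:
        raise KeyError(f"anchor protein {spec.anchor_id!r} absent")
    anchor_mean = float(normalized.loc[spec.anchor_id].mean())
    if not anchor_mean > 0:
        raise ValueError("anchor protein has zero mean normalized intensity")
    fmol_per_ul = normalized * (spec.anchor_amount / anchor_mean)
    return fmol_per_ul * MOLECULES_PER_FMOL / spec.cells_per_volume


# ---------------------------------------------------------------------------
# complex stoichiometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexDefinition:
    """Named protein complex with integer per-subunit stoichiometry."""

    name: str
    subunits: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.subunits:
            raise ValueError("complex must have at least one subunit")
        for sub, coeff in self.subunits.items():
            if not (isinstance(coeff, int) and coeff >= 1):
                raise ValueError(
                    f"stoichiometric coefficient of {sub} must be an "
                    f"integer >= 1, got {coeff!r}")


class StoichiometryParseError(ValueError):
    def __init__(self, message: str, text: str, pos: int):
        super().__init__(f"{message} at position {pos} in {text!r}")
        self.pos = pos


_LOCUS = re.compile(r"^([Ss][lsr][lr]\d{4})(\d*)$")
_FULLNAME = re.compile(r"^[A-Z][a-z]")
_PREFIX = re.compile(r"^([A-Z][a-z]+)")


def parse_stoichiometry(text: str, name: str = "") -> ComplexDefinition:
    """Parse a compact complex formula into per-subunit coefficients.

    Grammar: comma (or ``/``) separated items; an item is a parenthesized
    group with an optional integer multiplier, or a subunit token.
    Tokens starting uppercase+lowercase (``RbcL``) are full names and set
    the running prefix; short forms (``B``, ``A2``, ``1B``) inherit it, so
    ``(PsaA,B,C)3`` means PsaA, PsaB, PsaC three times each.  Outside
    groups a trailing digit run is the stoichiometric subscript
    (``TktA2`` = TktA x2), with two exceptions: locus tags keep their four
    digits (``Slr20944`` = Slr2094 x4) and an explicit ``Name*count``
    overrides the heuristic.  Inside groups digits are part of the name
    (isoforms such as ``PsbA1``); multiplicity comes from the group
    multiplier.

    >>> parse_stoichiometry("(RbcL, RbcS)8").subunits
    {'RbcL': 8, 'RbcS': 8}
    """
    state = {"prefix": ""}
    items, pos = _parse_items(text, 0, state, depth=0)
    if pos != len(text):
        raise StoichiometryParseError("unexpected trailing input", text, pos)
    merged: dict[str, int] = {}
    for sub, coeff in items:
        merged[sub] = merged.get(sub, 0) + coeff
    return ComplexDefinition(name=name or text.strip(), subunits=merged)


def _parse_items(text: str, pos: int, state: dict, depth: int
                 ) -> tuple[list[tuple[str, int]], int]:
    items: list[tuple[str, int]] = []
    expect_item = True
    while pos < len(text):
        ch = text[pos]
        if ch.isspace():
            pos += 1
        elif ch in ",/":
            if expect_item:
                raise StoichiometryParseError("empty item", text, pos)
            expect_item = True
            pos += 1
        elif ch == "(":
            inner, pos = _parse_items(text, pos + 1, state, depth + 1)
            if pos >= len(text) or text[pos] != ")":
                raise StoichiometryParseError("unbalanced '('", text, pos)
            pos += 1
            mult, pos = _read_int(text, pos)
            items.extend((s, c * (mult or 1)) for s, c in inner)
            expect_item = False
        elif ch == ")":
            if depth == 0:
                raise StoichiometryParseError("unbalanced ')'", text, pos)
            return items, pos
        else:
            token, pos = _read_token(text, pos)
            items.append(_resolve_token(token, state, in_group=depth > 0,
                                        text=text, pos=pos))
            expect_item = False
    if depth > 0:
        raise StoichiometryParseError("unbalanced '('", text, pos)
    if expect_item and items:
        raise StoichiometryParseError("trailing separator", text, pos)
    if not items:
        raise StoichiometryParseError("empty formula", text, pos)
    return items, pos


def _read_token(text: str, pos: int) -> tuple[str, int]:
    start = pos
    while pos < len(text) and (text[pos].isalnum() or text[pos] == "*"):
        pos += 1
    if pos == start:
        raise StoichiometryParseError(f"unexpected character {text[pos]!r}",
                                      text, pos)
    return text[start:pos], pos


def _read_int(text: str, pos: int) -> tuple[int | None, int]:
    start = pos
    while pos < len(text) and text[pos].isdigit():
        pos += 1
    return (int(text[start:pos]) if pos > start else None), pos


def _resolve_token(token: str, state: dict, in_group: bool,
                   text: str, pos: int) -> tuple[str, int]:
    if "*" in token:
        name_part, _, count_part = token.partition("*")
        if not name_part or not count_part.isdigit():
            raise StoichiometryParseError(f"malformed token {token!r}",
                                          text, pos)
        name, count = name_part, int(count_part)
        if _FULLNAME.match(name):
            m = _PREFIX.match(name)
            state["prefix"] = m.group(1) if m else ""
        return name, count
    locus = _LOCUS.match(token)
    if locus:
        state["prefix"] = ""
        return locus.group(1), int(locus.group(2)) if locus.group(2) else 1
    if _FULLNAME.match(token):
        m = _PREFIX.match(token)
        state["prefix"] = m.group(1) if m else ""
        name = token
    else:  # short form: inherit the running prefix
        name = state["prefix"] + token
    if in_group:
        return name, 1
    m = re.match(r"^(.*?[A-Za-z])(\d*)$", name)
    if not m:
        raise StoichiometryParseError(f"malformed token {token!r}", text, pos)
    return m.group(1), int(m.group(2)) if m.group(2) else 1


def load_complex_library() -> dict[str, ComplexDefinition]:
    """The packaged library of curated complex stoichiometries."""
    ref = resources.files("cyanoecon.data").joinpath("complexes.tsv")
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    return {row["name"]: parse_stoichiometry(row["formula"], name=row["name"])
            for _, row in table.iterrows()}


# ---------------------------------------------------------------------------
# complex copy numbers
# ---------------------------------------------------------------------------

@dataclass
class ComplexCopyNumber:
    """Copy-number estimate of one complex in one condition."""

    name: str
    weighted: float         # sum(copies_i) / sum(s_i) over quantified
    lower_bound: float      # min_i copies_i / s_i (conservative)
    upper_bound: float      # max_i copies_i / s_i
    n_quantified: int
    missing_subunits: list[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.n_quantified > 0


def complex_copy_number(copies_per_cell: Mapping[str, float] | pd.Series,
                        cx: ComplexDefinition) -> ComplexCopyNumber:
    """Stoichiometry-weighted complex copy number from subunit copies.

    The weighted estimate sum(copies_i)/sum(s_i) over quantified subunits
    is robust to single-subunit ionization bias; the per-subunit ratios
    copies_i/s_i give conservative lower/upper bounds.  Missing subunits
    are listed; a complex with no quantified subunit is returned undefined
    (NaN estimates) rather than raising.
    """
    got: dict[str, float] = {}
    missing: list[str] = []
    for sub, coeff in cx.subunits.items():
        val = copies_per_cell.get(sub) if hasattr(copies_per_cell, "get") \
            else copies_per_cell[sub]
        if val is None or (isinstance(val, float) and math.isnan(val)):
            missing.append(sub)
        else:
            got[sub] = float(val)
    if not got:
        return ComplexCopyNumber(cx.name, float("nan"), float("nan"),
                                 float("nan"), 0, missing)
    ratios = [got[s] / cx.subunits[s] for s in got]
    weighted = sum(got.values()) / sum(cx.subunits[s] for s in got)
    return ComplexCopyNumber(cx.name, weighted, min(ratios), max(ratios),
                             len(got), missing)


def complex_table(copies_by_condition: Mapping[str, Mapping[str, float]],
                  library: Mapping[str, ComplexDefinition] | None = None,
                  ) -> pd.DataFrame:
    """Per-complex copy-number ranges across conditions.

    ``copies_by_condition`` maps condition label -> per-protein copies.
    Reports the min/max of the weighted estimate across conditions.
    """
    library = library or load_complex_library()
    rows = []
    for name, cx in library.items():
        ests = []
        for cond, copies in copies_by_condition.items():
            est = complex_copy_number(copies, cx)
            if est.defined:
                ests.append(est.weighted)
        rows.append({
            "complex": name,
            "copies_min": min(ests) if ests else float("nan"),
            "copies_max": max(ests) if ests else float("nan"),
            "method": "proteomics (stoichiometry-weighted iBAQ)",
        })
    return pd.DataFrame(rows)
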