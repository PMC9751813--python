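"""Accurate-mass annotation of (oxidized) lipid features.

LC-MS features from aged seed extracts are annotated by matching their
observed m/z against the theoretical singly charged adduct masses
([M+H]+, [M+NH4]+, [M+Na]+) of candidate lipid formulas within a 3 ppm
gate.  Oxidized species are named in the ``class c:d + nO`` convention —
e.g. ``TAG 52:3 + 2 O`` is a triacylglycerol with 52 acyl carbons, 3 double
bonds and two oxygen atoms incorporated beyond the ester backbone.

Monoisotopic masses come from the IUPAC isotope tables via pyteomics; the
adduct deltas fold in the electron mass (proton = 1.007276 Da), so no
separate charge correction is applied.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pmass
from pyteomics.auxiliary import PyteomicsError

__all__ = [
    "ADDUCT_DELTAS",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "LipidAnnotation",
    "classify_lipid",
    "lipid_label",
    "MatchCandidate",
    "match_feature",
    "build_tag_library",
    "double_bond_equivalents",
]

#: Singly charged adduct mass deltas in Da (electron mass included).
ADDUCT_DELTAS: dict[str, float] = {
    "protonated": 1.007276,  # [M+H]+
    "ammoniated": 18.034374,  # [M+NH4]+
    "sodiated": 22.989218,  # [M+Na]+
}

DEFAULT_TOLERANCE_PPM = 3.0

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse ``"C55H100O8"`` into element counts; mappings pass through."""
    if isinstance(formula, Mapping):
        counts = {el: int(n) for el, n in formula.items() if n}
    else:
        if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
            raise ValueError(f"malformed elemental formula: {formula!r}")
        counts = {}
        for el, num in _FORMULA_RE.findall(formula):
            if el:
                counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if not counts or all(v == 0 for v in counts.values()):
        raise ValueError("formula must contain at least one atom")
    if any(v < 0 for v in counts.values()):
        raise ValueError("element counts must be non-negative")
    return counts


def formula_string(counts: Mapping[str, int]) -> str:
    """Hill-order string (C, H, then alphabetical) for element counts."""
    parts = []
    order = ["C", "H"] + sorted(k for k in counts if k not in ("C", "H"))
    for el in order:
        n = counts.get(el, 0)
        if n:
            parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral formula, Da."""
    counts = parse_formula(formula)
    try:
        return float(_pmass.calculate_mass(composition=counts))
    except PyteomicsError as exc:  # unknown element symbol
        raise ValueError(f"cannot compute mass for {formula!r}: {exc}") from exc


def adduct_mz(formula: str | Mapping[str, int], adduct: str) -> float:
    """Theoretical m/z of a singly charged adduct of a neutral formula."""
    if adduct not in ADDUCT_DELTAS:
        raise ValueError(
            f"unknown adduct {adduct!r}; known: {sorted(ADDUCT_DELTAS)}"
        )
    return monoisotopic_mass(formula) + ADDUCT_DELTAS[adduct]


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed mass deviation in parts per million."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be positive")
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz


def double_bond_equivalents(counts: Mapping[str, int]) -> float:
    """DBE = (2C + 2 + N − H) / 2 (rings plus double bonds)."""
    c = counts.get("C", 0)
    h = counts.get("H", 0)
    n = counts.get("N", 0)
    return (2 * c + 2 + n - h) / 2


# ---------------------------------------------------------------------------
# class rules: (base oxygens, base nitrogens, carbons offset, DBE offset)
# c = C - c_offset ; d = DBE - dbe_offset ; nO = O - base_O
# TAG/DAG subtract the glycerol backbone carbons; a free FA keeps them all.
_CLASS_RULES: dict[str, tuple[int, int, int, int]] = {
    "TAG": (6, 0, 3, 3),
    "DAG": (5, 0, 3, 2),
    "FA": (2, 0, 0, 1),
}
#: Ethanolamide of a fatty acid (e.g. anandamide-type species); optional.
_AMIDE_RULE = ("FA-amide", 2, 1, 2, 2)

_CLASS_ORDER = {"TAG": 0, "DAG": 1, "FA": 2, "FA-amide": 3}

#: Plausible total acyl-carbon ranges per class in seed lipidomes; candidates
#: inside their class range outrank out-of-range readings of the same formula.
_PLAUSIBLE_CARBONS = {
    "TAG": (30, 66),
    "DAG": (20, 44),
    "FA": (8, 28),
    "FA-amide": (8, 28),
}

#: Trivial names for common free fatty acids (c, d) -> name.
FATTY_ACID_NAMES = {
    (16, 0): "Palmitic acid",
    (18, 0): "Stearic acid",
    (18, 1): "Oleic acid",
    (18, 2): "Linoleic acid",
    (18, 3): "Linolenic acid",
}


@dataclass(frozen=True)
class LipidAnnotation:
    """A ``class c:d + nO`` reading of an elemental formula."""

    lipid_class: str
    carbons: int  # acyl carbons c
    double_bonds: int  # d
    extra_oxygens: int  # nO
    formula: str
    theoretical_mz: float = math.nan
    adduct: str | None = None
    ppm: float = math.nan

    @property
    def label(self) -> str:
        return lipid_label(
            self.lipid_class, self.carbons, self.double_bonds, self.extra_oxygens
        )


def lipid_label(lipid_class: str, c: int, d: int, n_o: int) -> str:
    """Render the ``class c:d + nO`` annotation string.

    Free fatty acids with a trivial name are labelled by it
    (``"Oleic acid + 3 O"``); zero added oxygens are omitted
    (``"TAG 54:8"``).
    """
    if lipid_class == "FA" and (c, d) in FATTY_ACID_NAMES:
        base = FATTY_ACID_NAMES[(c, d)]
    else:
        base = f"{lipid_class} {c}:{d}"
    return f"{base} + {n_o} O" if n_o > 0 else base


def classify_lipid(
    formula: str | Mapping[str, int], include_amide: bool = True
) -> list[LipidAnnotation]:
    """Read an elemental formula as lipid ``class c:d + nO`` candidates.

    Each supported class fixes a backbone oxygen count; the acyl carbons,
    double bonds and added oxygens then follow from the formula and its
    double-bond equivalents.  All classes yielding non-negative ``(d, nO)``
    are returned, ranked by chemical plausibility: readings whose acyl
    carbons fall in the class's typical range come first, then the class
    order TAG > DAG > FA.  An empty list means the formula fits no
    supported class.
    """
    counts = parse_formula(formula)
    if counts.get("O", 0) < 2:
        return []
    dbe = double_bond_equivalents(counts)
    if dbe != int(dbe) or dbe < 0:
        return []  # radical/charged formula: not a neutral lipid
    dbe = int(dbe)
    n_c, n_o, n_n = counts.get("C", 0), counts.get("O", 0), counts.get("N", 0)

    rules = [(name, *r) for name, r in _CLASS_RULES.items()]
    if include_amide:
        rules.append(_AMIDE_RULE)
    out = []
    for name, base_o, base_n, c_off, dbe_off in rules:
        if n_n != base_n:
            continue
        c = n_c - c_off
        d = dbe - dbe_off
        extra = n_o - base_o
        if c <= 0 or d < 0 or extra < 0:
            continue
        out.append(
            LipidAnnotation(
                lipid_class=name,
                carbons=c,
                double_bonds=d,
                extra_oxygens=extra,
                formula=formula_string(counts),
            )
        )
    def _rank(a: LipidAnnotation):
        lo, hi = _PLAUSIBLE_CARBONS[a.lipid_class]
        return (not lo <= a.carbons <= hi, _CLASS_ORDER[a.lipid_class])

    out.sort(key=_rank)
    return out


# ---------------------------------------------------------------------------
# matching


@dataclass(frozen=True)
class MatchCandidate:
    """A library entry: neutral formula plus the adduct to consider."""

    formula: str
    adduct: str
    label: str = ""


def match_feature(
    observed_mz: float,
    candidates: Sequence[MatchCandidate | tuple],
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
) -> list[LipidAnnotation]:
    """Accept library candidates whose adduct m/z lies within the ppm gate.

    Returns annotations sorted by absolute ppm error; ties are broken by
    fewer added oxygens, then lower double-bond count.  An empty list means
    the feature stays an "unknown".
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    accepted = []
    for cand in candidates:
        if isinstance(cand, tuple):
            cand = MatchCandidate(*cand)
        theo = adduct_mz(cand.formula, cand.adduct)
        ppm = ppm_error(observed_mz, theo)
        if abs(ppm) > tolerance_ppm:
            continue
        classes = classify_lipid(cand.formula)
        if classes:
            base = classes[0]
            ann = LipidAnnotation(
                lipid_class=base.lipid_class,
                carbons=base.carbons,
                double_bonds=base.double_bonds,
                extra_oxygens=base.extra_oxygens,
                formula=base.formula,
                theoretical_mz=theo,
                adduct=cand.adduct,
                ppm=ppm,
            )
        else:
            ann = LipidAnnotation(
                lipid_class=cand.label or "other",
                carbons=0,
                double_bonds=0,
                extra_oxygens=0,
                formula=formula_string(parse_formula(cand.formula)),
                theoretical_mz=theo,
                adduct=cand.adduct,
                ppm=ppm,
            )
        accepted.append(ann)
    # group ppm to 1e-4 so float dust cannot decide between true ties
    accepted.sort(
        key=lambda a: (round(abs(a.ppm), 4), a.extra_oxygens, a.double_bonds)
    )
    return accepted


def tag_formula(c: int, d: int, n_o: int = 0) -> str:
    """Elemental formula of a triacylglycerol ``TAG c:d + nO``.

    Total carbons ``c + 3`` (glycerol backbone), oxygens ``6 + nO``, and
    hydrogens fixed by the DBE ``d + 3`` (three ester carbonyls).
    """
    if c <= 0 or d < 0 or n_o < 0:
        raise ValueError("invalid TAG descriptor")
    n_c = c + 3
    h = 2 * n_c + 2 - 2 * (d + 3)
    if h <= 0:
        raise ValueError("unsaturated beyond a valid formula")
    return formula_string({"C": n_c, "H": h, "O": 6 + n_o})


def build_tag_library(
    carbons: Iterable[int] = range(40, 61, 2),
    double_bonds: Iterable[int] = range(0, 9),
    extra_oxygens: Iterable[int] = range(0, 5),
    adducts: Iterable[str] = ("protonated", "ammoniated"),
) -> list[MatchCandidate]:
    """Enumerate a TAG candidate library (base species × added oxygens).

    Library-based candidate generation mirrors how lipidomics features are
    matched against curated databases and avoids the combinatorial false
    positives of free formula decomposition.
    """
    lib = []
    for c, d, n_o in itertools.product(carbons, double_bonds, extra_oxygens):
        try:
            f = tag_formula(c, d, n_o)
        except ValueError:
            continue
        for add in adducts:
            lib.append(MatchCandidate(formula=f, adduct=add, label=f"TAG {c}:{d}"))
    return lib
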