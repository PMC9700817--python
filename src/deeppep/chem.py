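"""Elemental masses, composition strings and amino-acid residue masses.

The element vocabulary is frozen: the six elements C, H, N, O, S, P that
dominate peptide chemistry come first, followed by 22 further symbols
(halogens, biologically relevant metals and the common stable-isotope
labels) that occur in modification compositions.  The fixed order matters:
the first six positions feed the raw CHNOSP channels of the PTM embedding
and the remaining 22 feed its learned two-unit projection, so the list is
part of the frozen model dimensions and must not be reordered.
"""

from __future__ import annotations

import re

from pyteomics import mass as _pt_mass

#: CHNOSP first (raw PTM-embedding channels), then the extended vocabulary.
CHNOSP: tuple[str, ...] = ("C", "H", "N", "O", "S", "P")

OTHER_ELEMENTS: tuple[str, ...] = (
    "13C", "15N", "2H", "18O",           # stable-isotope labels
    "F", "Cl", "Br", "I",                # halogens
    "Na", "K", "Ca", "Mg", "Li",         # alkali / alkaline-earth adducts
    "Fe", "Zn", "Cu", "Mn", "Ni", "Co",  # transition metals
    "Se", "Mo", "B",                     # selenium, molybdenum, boron
)

ELEMENTS: tuple[str, ...] = CHNOSP + OTHER_ELEMENTS

_ISOTOPE_RE = re.compile(r"^(\d+)([A-Z][a-z]?)$")


def _element_mono_mass(symbol: str) -> float:
    m = _ISOTOPE_RE.match(symbol)
    if m:
        iso, el = int(m.group(1)), m.group(2)
        return _pt_mass.nist_mass[el][iso][0]
    # index 0 holds the most abundant (monoisotopic) mass
    return _pt_mass.nist_mass[symbol][0][0]


#: Monoisotopic mass of every supported element symbol, in Da.
MONO_MASS: dict[str, float] = {el: _element_mono_mass(el) for el in ELEMENTS}

MASS_PROTON = 1.007276466621
MASS_H2O = MONO_MASS["H"] * 2 + MONO_MASS["O"]

#: Monoisotopic residue masses.  Ambiguity codes and rare residues without a
#: defined default mass (B, J, O, U, X, Z) are deliberately absent.
AA_MONO_MASS: dict[str, float] = {
    aa: m for aa, m in _pt_mass.std_aa_mass.items()
    if len(aa) == 1 and aa not in set("BJOUXZ")
}

_COMP_RE = re.compile(r"(\d*[A-Z][a-z]?)(?:\((-?\d+)\))?")


def parse_composition(text: str) -> dict[str, int]:
    """Parse a composition string like ``"H(1)O(3)P(1)"`` into counts.

    A missing count means 1; negative counts are allowed (e.g. ``"H(-1)"``
    for dehydration).  Element symbols may carry isotope prefixes
    (``"13C(6)"``).
    """
    if not text:
        return {}
    comp: dict[str, int] = {}
    pos = 0
    for m in _COMP_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"invalid composition string: {text!r}")
        pos = m.end()
        el = m.group(1)
        if el not in MONO_MASS:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        comp[el] = comp.get(el, 0) + int(m.group(2) or 1)
    if pos != len(text):
        raise ValueError(f"invalid composition string: {text!r}")
    return {el: n for el, n in comp.items() if n != 0}


def format_composition(comp: dict[str, int]) -> str:
    """Render counts as a composition string with elements in frozen order."""
    order = {el: i for i, el in enumerate(ELEMENTS)}
    return "".join(
        f"{el}({comp[el]})" for el in sorted(comp, key=order.__getitem__)
    )


def composition_mass(comp: dict[str, int]) -> float:
    """Monoisotopic mass (Da) of an elemental composition."""
    unknown = [el for el in comp if el not in MONO_MASS]
    if unknown:
        raise ValueError(f"unknown element symbol(s): {unknown}")
    return sum(MONO_MASS[el] * n for el, n in comp.items())
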