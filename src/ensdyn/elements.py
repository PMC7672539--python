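"""Fixed element parameter table.

Masses are IUPAC 2021 standard atomic weights (amu).  Van der Waals radii
are Bondi (1964) values, with the Rowland & Taylor (1996) revision for
hydrogen.  The table is shipped with the package so that every downstream
quantity (entropy, contact areas) is reproducible bit-for-bit without an
external parameter source.
"""

from __future__ import annotations

#: element symbol -> (mass in amu, van der Waals radius in Angstrom)
ELEMENT_TABLE: dict[str, tuple[float, float]] = {
    "H": (1.008, 1.10),
    "C": (12.011, 1.70),
    "N": (14.007, 1.55),
    "O": (15.999, 1.52),
    "S": (32.06, 1.80),
    "P": (30.974, 1.80),
    "F": (18.998, 1.47),
    "CL": (35.45, 1.75),
    "BR": (79.904, 1.85),
    "I": (126.904, 1.98),
    "SE": (78.971, 1.90),
    "FE": (55.845, 2.00),
    "ZN": (65.38, 1.39),
    "MG": (24.305, 1.73),
    "CA": (40.078, 2.31),
    "NA": (22.990, 2.27),
    "K": (39.098, 2.75),
}


class UnknownElementError(KeyError):
    """Raised when an atom's element symbol is not in the parameter table."""


def element_params(symbol: str) -> tuple[float, float]:
    """Return ``(mass, vdw_radius)`` for an element symbol (case-insensitive)."""
    try:
        return ELEMENT_TABLE[symbol.strip().upper()]
    except KeyError:
        raise UnknownElementError(
            f"element {symbol!r} is not in the internal parameter table; "
            f"known elements: {sorted(ELEMENT_TABLE)}"
        ) from None


def guess_element(atom_name: str) -> str:
    """Guess the element from a PDB atom name when columns 77-78 are blank.

    Uses the PDB convention that a two-character element name occupies the
    first two columns of the name field; otherwise the first alphabetic
    character is the element.
    """
    name = atom_name.strip()
    if len(name) >= 2 and name[:2].upper() in ELEMENT_TABLE and name[:2].isalpha():
        # Avoid misreading "CA" (alpha carbon) / "CB" etc. as calcium:
        # two-letter elements are only accepted for names that are exactly
        # the element symbol (ions like "ZN", "FE").
        if name.upper() in ELEMENT_TABLE and name.upper() not in ("CA", "CB", "CD", "CE", "NA"):
            return name.upper()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise UnknownElementError(f"cannot infer element from atom name {atom_name!r}")
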