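"""Element metadata (masses, radii, atomic numbers) backed by gemmi's tables.

Unknown symbols are rejected rather than silently defaulted, so every atom
that enters the pipeline has a defined mass and van der Waals radius.
"""

from __future__ import annotations

import gemmi

__all__ = [
    "is_known_element",
    "normalize_symbol",
    "atomic_number",
    "atomic_mass",
    "vdw_radius",
    "covalent_radius",
]


def normalize_symbol(symbol: str) -> str:
    """Return the canonical capitalisation of a chemical symbol.

    Raises ``ValueError`` for symbols gemmi does not recognise.
    """
    sym = symbol.strip()
    if not sym:
        raise ValueError("empty element symbol")
    el = gemmi.Element(sym)
    # gemmi maps unknown strings to the dummy element 'X' (Z = 0)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element symbol: {symbol!r}")
    return el.name


def is_known_element(symbol: str) -> bool:
    try:
        normalize_symbol(symbol)
    except ValueError:
        return False
    return True


def atomic_number(symbol: str) -> int:
    return gemmi.Element(normalize_symbol(symbol)).atomic_number


def atomic_mass(symbol: str) -> float:
    """Standard atomic weight in amu."""
    return gemmi.Element(normalize_symbol(symbol)).weight


def vdw_radius(symbol: str) -> float:
    """Van der Waals radius in Angstrom."""
    return gemmi.Element(normalize_symbol(symbol)).vdw_r


def covalent_radius(symbol: str) -> float:
    """Covalent radius in Angstrom."""
    return gemmi.Element(normalize_symbol(symbol)).covalent_r
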