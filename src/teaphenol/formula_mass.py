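"""Elemental-formula arithmetic: monoisotopic masses, [M−H]− m/z, ppm errors, RDB.

All calculated m/z values in the annotation layer come from this module. Atomic
masses are pinned 7-decimal constants shipped in ``data/atomic_masses.tsv`` so
that every reported value is bit-stable across platforms.

Conventions
-----------
* ``[M−H]−`` m/z is the neutral monoisotopic mass minus the proton mass
  (1.007276 Da); the electron mass is neglected, which reproduces 4-decimal
  reference values for negative-mode QqTOF data.
* ppm error is signed as ``(found − calc) / calc × 1e6``.
* Reported values are rounded half-up: 4 decimals for m/z, 1 for ppm.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from typing import Iterator, Mapping

__all__ = [
    "PROTON_MASS",
    "ATOMIC_MASSES",
    "ElementalFormula",
    "IonRecord",
    "parse_formula",
    "monoisotopic_mass",
    "deprotonated_mz",
    "radical_mz",
    "ppm_error",
    "rdb",
    "round_half_up",
]

#: Mass of a proton, Da. Subtracted from the neutral mass for [M−H]−.
PROTON_MASS = 1.007276

#: Mass of a hydrogen atom, Da (used for the [M−2H]•− radical species).
HYDROGEN_ATOM_MASS = 1.0078250


def _load_atomic_masses() -> dict[str, float]:
    text = (resources.files("teaphenol.data") / "atomic_masses.tsv").read_text()
    masses: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbol, mass = line.split("\t")
        masses[symbol] = float(mass)
    return masses


#: Monoisotopic atomic masses, Da, keyed by element symbol.
ATOMIC_MASSES: Mapping[str, float] = _load_atomic_masses()

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def round_half_up(x: float, decimals: int) -> float:
    """Round ``x`` half-up to ``decimals`` places (table-style rounding)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable element → count map.

    Equality is count-map equality; zero counts are dropped so C15H14O6 and
    C15H14N0O6 compare equal.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        cleaned: dict[str, int] = {}
        for element, n in self.counts.items():
            if element not in ATOMIC_MASSES:
                raise ValueError(f"unknown element symbol: {element!r}")
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {element} must be a non-negative integer, got {n!r}")
            if n > 0:
                cleaned[element] = n
        object.__setattr__(self, "counts", cleaned)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            merged[element] = merged.get(element, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            merged[element] = merged.get(element, 0) - n
            if merged[element] < 0:
                raise ValueError(f"subtraction drives {element} below zero")
        return ElementalFormula(merged)

    def hill(self) -> str:
        """Canonical Hill-order string: C first, H second, then alphabetical."""
        parts = []
        for element in _hill_order(self.counts):
            n = self.counts[element]
            parts.append(element + (str(n) if n != 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def _hill_order(counts: Mapping[str, int]) -> list[str]:
    rest = sorted(e for e in counts if e not in ("C", "H"))
    head = [e for e in ("C", "H") if e in counts]
    return head + rest


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C15H14O6"``.

    An omitted count means 1. Raises ``ValueError`` on unknown element symbols
    or explicit zero counts, and on any stray characters.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"unparsable formula segment at {text[pos:match.start()]!r} in {text!r}")
        pos = match.end()
        element, digits = match.groups()
        if element not in ATOMIC_MASSES:
            raise ValueError(f"unknown element symbol: {element!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise ValueError(f"zero count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + n
    if pos != len(text):
        raise ValueError(f"unparsable formula segment at {text[pos:]!r} in {text!r}")
    return ElementalFormula(counts)


def monoisotopic_mass(f: ElementalFormula | str) -> float:
    """Neutral monoisotopic mass in Da (exact sum of pinned atomic masses)."""
    if isinstance(f, str):
        f = parse_formula(f)
    if not f.counts:
        raise ValueError("empty formula has no mass")
    return sum(n * ATOMIC_MASSES[e] for e, n in f.counts.items())


def deprotonated_mz(f: ElementalFormula | str, *, decimals: int | None = None) -> float:
    """m/z of the deprotonated molecular ion [M−H]−.

    With ``decimals`` set (typically 4) the value is rounded half-up for
    report-style output; by default the full-precision float is returned.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    if f["H"] < 1:
        raise ValueError("deprotonation requires at least one hydrogen")
    mz = monoisotopic_mass(f) - PROTON_MASS
    return round_half_up(mz, decimals) if decimals is not None else mz


def radical_mz(f: ElementalFormula | str, *, decimals: int | None = None) -> float:
    """m/z of the odd-electron radical anion [M−2H]•−.

    One hydrogen atom lighter than the even-electron [M−H]− ion; formed e.g.
    by homolytic glycosidic cleavage of flavonol 3-O-glycosides.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    if f["H"] < 2:
        raise ValueError("radical anion requires at least two hydrogens")
    mz = monoisotopic_mass(f) - PROTON_MASS - HYDROGEN_ATOM_MASS
    return round_half_up(mz, decimals) if decimals is not None else mz


def ppm_error(found_mz: float, calc_mz: float, *, decimals: int | None = 1) -> float:
    """Signed relative mass error, (found − calc)/calc × 1e6, in ppm."""
    if calc_mz <= 0:
        raise ValueError("calc_mz must be positive")
    ppm = (found_mz - calc_mz) / calc_mz * 1e6
    return round_half_up(ppm, decimals) if decimals is not None else ppm


def rdb(f: ElementalFormula | str) -> float:
    """Ring-plus-double-bond equivalents: C − H/2 + N/2 + 1.

    Halogens count like hydrogen; O/S are neutral. Returns a half-integer for
    odd-electron compositions.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    h_like = f["H"] + f["Cl"]
    return f["C"] - h_like / 2 + f["N"] / 2 + 1


@dataclass(frozen=True)
class IonRecord:
    """A calculated ion: formula, ion species, m/z and RDB of the neutral."""

    formula: ElementalFormula
    species: str = "[M-H]-"
    calc_mz: float = field(init=False, default=0.0)
    rdb: float = field(init=False, default=0.0)

    _SPECIES = ("[M-H]-", "[M-2H]-.", "neutral")

    def __post_init__(self) -> None:
        if self.species not in self._SPECIES:
            raise ValueError(f"species must be one of {self._SPECIES}")
        if self.species == "[M-H]-":
            mz = deprotonated_mz(self.formula)
        elif self.species == "[M-2H]-.":
            mz = radical_mz(self.formula)
        else:
            mz = monoisotopic_mass(self.formula)
        object.__setattr__(self, "calc_mz", mz)
        object.__setattr__(self, "rdb", rdb(self.formula))
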