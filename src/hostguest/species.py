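"""Host-guest ion species: composition, m/z, enumeration, bracket labels.

An ESI ion of a host-guest mixture is modelled as

    a·Host + b·Guest + nH·H + nNa·Na,  net charge z = nH + nNa

i.e. all charge is carried by protonation/deprotonation (nH, which may be
negative) or sodiation (nNa ≥ 0). Sodium salts of the guest are not separate
species: AlnNa ≡ AlnH + Na − H is absorbed into the nH/nNa bookkeeping, so
"[βCD + 2AlnNa + 2H]2+" and "[βCD + 2AlnH + 2Na]2+" denote one ion with one
canonical label.

m/z includes the electron-mass correction (−z·mₑ): 0.55 mDa per charge,
which matters at the 3-decimal precision of TOF peak lists.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

from .formula import (
    ELECTRON_MASS,
    ELEMENTS,
    ElementalFormula,
    monoisotopic_mass,
    parse_formula,
)

__all__ = [
    "MolecularSpecies",
    "IonSpecies",
    "EnumerationBounds",
    "mz_of_ion",
    "enumerate_ions",
    "ion_label",
    "parse_ion_label",
    "PROTON_SPACING",
]

_M_H = ELEMENTS["H"].monoisotopic_mass
_M_NA = ELEMENTS["Na"].monoisotopic_mass

#: m/z spacing between consecutive isotopologues of a singly charged CHNOP ion.
PROTON_SPACING = 1.00336


@dataclass(frozen=True)
class MolecularSpecies:
    """A neutral molecule taking part in ion formation (host, guest, fragment)."""

    name: str
    formula: ElementalFormula

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("species name must be non-empty")
        if not self.formula:
            raise ValueError(f"species {self.name!r} has an empty formula")

    @classmethod
    def from_string(cls, name: str, formula: str) -> "MolecularSpecies":
        return cls(name, parse_formula(formula))


@dataclass(frozen=True)
class IonSpecies:
    """An adduct ion: multiset of neutral components plus H/Na charge carriers.

    ``components`` maps each :class:`MolecularSpecies` to its count (≥ 1);
    ``nH`` is the number of hydrogen atoms added (negative = deprotonation),
    ``nNa`` the number of sodium atoms added (≥ 0), and ``z`` the signed
    charge, constrained to ``z = nH + nNa`` with ``|z| ≥ 1``.
    """

    components: tuple[tuple[MolecularSpecies, int], ...]
    nH: int = 0
    nNa: int = 0
    z: int = 1

    def __post_init__(self) -> None:
        if not self.components or all(n == 0 for _, n in self.components):
            raise ValueError("ion must contain at least one neutral component")
        if any(n < 0 for _, n in self.components):
            raise ValueError("component counts must be non-negative")
        object.__setattr__(
            self, "components", tuple((s, n) for s, n in self.components if n > 0)
        )
        if self.nNa < 0:
            raise ValueError("nNa must be non-negative")
        if self.z == 0 or abs(self.z) < 1:
            raise ValueError("charge must be nonzero")
        if self.z != self.nH + self.nNa:
            raise ValueError(
                f"charge bookkeeping violated: z={self.z} != nH+nNa="
                f"{self.nH + self.nNa}"
            )

    @property
    def formula(self) -> ElementalFormula:
        """Elemental formula of the intact ion (charge carriers included)."""
        f = ElementalFormula()
        for sp, n in self.components:
            f = f + n * sp.formula
        h = f.get("H") + self.nH
        if h < 0:
            raise ValueError(
                f"deprotonation drives hydrogen count negative ({h}) in "
                f"{ion_label(self)}"
            )
        counts = dict(f.counts)
        counts["H"] = h
        counts["Na"] = counts.get("Na", 0) + self.nNa
        return ElementalFormula(counts)

    @property
    def n_components(self) -> int:
        return sum(n for _, n in self.components)


def mz_of_ion(ion: IonSpecies) -> float:
    """Theoretical monoisotopic m/z (Th), electron-corrected.

    m/z = (Σ aᵢ·Mᵢ + nH·m(H) + nNa·m(Na) − z·mₑ) / |z|
    """
    neutral = sum(monoisotopic_mass(sp.formula) * n for sp, n in ion.components)
    m = neutral + ion.nH * _M_H + ion.nNa * _M_NA - ion.z * ELECTRON_MASS
    # triggers the negative-hydrogen check for over-deprotonated candidates
    ion.formula
    mz = m / abs(ion.z)
    if mz <= 0:
        raise ValueError("non-positive m/z")
    return mz


@dataclass(frozen=True)
class EnumerationBounds:
    """Search-space bounds for candidate ion enumeration."""

    max_host: int = 4
    max_guest: int = 4
    max_na: int = 4
    max_charge: int = 3
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if min(self.max_host, self.max_guest, self.max_na, self.max_charge) < 0:
            raise ValueError("bounds must be non-negative")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")


def enumerate_ions(
    species: list[MolecularSpecies], bounds: EnumerationBounds
) -> list[IonSpecies]:
    """All distinct ions within bounds, sorted by (m/z, label).

    ``species`` is ``[host, guest]`` (a guest-less run may pass one species).
    Every combination of host count a ≤ max_host, guest count b ≤ max_guest
    (a + b ≥ 1), sodiation nNa ≤ max_na and charge 1 ≤ |z| ≤ max_charge of the
    requested polarity is emitted, with nH = z − nNa; combinations whose
    deprotonation exceeds the available hydrogens are dropped.
    """
    if not species:
        raise ValueError("species list is empty")
    host = species[0]
    guest = species[1] if len(species) > 1 else None
    sign = 1 if bounds.polarity == "positive" else -1
    out: list[IonSpecies] = []
    guest_range = range(bounds.max_guest + 1) if guest else [0]
    for a, b in itertools.product(range(bounds.max_host + 1), guest_range):
        if a + b == 0:
            continue
        comps = []
        if a:
            comps.append((host, a))
        if b and guest is not None:
            comps.append((guest, b))
        for zmag in range(1, bounds.max_charge + 1):
            for n_na in range(bounds.max_na + 1):
                ion = IonSpecies(tuple(comps), nH=sign * zmag - n_na,
                                 nNa=n_na, z=sign * zmag)
                try:
                    mz_of_ion(ion)
                except ValueError:
                    continue
                out.append(ion)
    out.sort(key=lambda i: (mz_of_ion(i), ion_label(i)))
    return out


def _count_prefix(n: int) -> str:
    return str(n) if n != 1 else ""


def ion_label(ion: IonSpecies) -> str:
    """Canonical bracket label, e.g. ``"[βCD + 2AlnH + H + Na]2+"``.

    Components in declaration order, then the H term, then the Na term, signs
    folded into the separators; charge as ``]z+``/``]z-`` with the magnitude
    omitted when 1. One canonical H/Na spelling per ion (guest sodium salts
    are not rendered as separate "AlnNa" components).
    """
    terms: list[tuple[int, str]] = []
    for sp, n in ion.components:
        terms.append((+1, f"{_count_prefix(n)}{sp.name}"))
    if ion.nH:
        terms.append((1 if ion.nH > 0 else -1, f"{_count_prefix(abs(ion.nH))}H"))
    if ion.nNa:
        terms.append((+1, f"{_count_prefix(ion.nNa)}Na"))
    body = terms[0][1] if terms[0][0] > 0 else "- " + terms[0][1]
    for sgn, text in terms[1:]:
        body += (" + " if sgn > 0 else " - ") + text
    zmag = abs(ion.z)
    return f"[{body}]{_count_prefix(zmag)}{'+' if ion.z > 0 else '-'}"


_LABEL_RE = re.compile(r"^\[(?P<body>[^\]]+)\](?P<zmag>\d*)(?P<sign>[+-])$")
_TERM_RE = re.compile(r"^(?P<count>\d*)(?P<name>.+)$")


def parse_ion_label(label: str, species: list[MolecularSpecies]) -> IonSpecies:
    """Parse a canonical bracket label back into an :class:`IonSpecies`.

    Inverse of :func:`ion_label` for labels over the given species registry;
    also accepts the hydrogen/sodium terms in either order.
    """
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"malformed ion label {label!r}")
    z = (int(m.group("zmag")) if m.group("zmag") else 1) * (
        1 if m.group("sign") == "+" else -1
    )
    registry = {sp.name: sp for sp in species}
    tokens = re.split(r"\s+([+-])\s+", m.group("body").strip())
    signed = [(+1, tokens[0])] + [
        (1 if tokens[i] == "+" else -1, tokens[i + 1])
        for i in range(1, len(tokens), 2)
    ]
    comps: dict[str, int] = {}
    nH = 0
    nNa = 0
    for sgn, tok in signed:
        tm = _TERM_RE.match(tok.strip())
        count = int(tm.group("count")) if tm.group("count") else 1
        name = tm.group("name")
        if name == "H":
            nH += sgn * count
        elif name == "Na":
            nNa += sgn * count
        elif name in registry:
            if sgn < 0:
                raise ValueError(f"negative component count in {label!r}")
            comps[name] = comps.get(name, 0) + count
        else:
            raise ValueError(f"unknown species {name!r} in label {label!r}")
    components = tuple((registry[n], c) for n, c in comps.items())
    return IonSpecies(components, nH=nH, nNa=nNa, z=z)
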