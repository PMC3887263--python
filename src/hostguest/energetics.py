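"""Complexation energies of host-guest inclusion complexes.

The complexation (binding) energy follows the supermolecule approach:

    ΔE = E_complex − (E_host + E_guest)

with all three total energies from the same level of theory. Negative ΔE
means inclusion is thermodynamically favorable; the lower the ΔE the more
stable the complex. Energies may be supplied in kcal/mol or hartree
(1 hartree = 627.5095 kcal/mol); ΔE is always reported in kcal/mol.
No basis-set superposition or solvation corrections are applied here — the
inputs are taken as-is from the upstream electronic-structure run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "HARTREE_TO_KCAL",
    "EnergyLedger",
    "delta_e",
    "compare_orientations",
]

HARTREE_TO_KCAL = 627.5095

_UNITS = ("kcal/mol", "hartree")


@dataclass(frozen=True)
class EnergyLedger:
    """Total energies of the complex and its isolated components."""

    e_complex: float
    e_host: float
    e_guest: float
    unit: str = "kcal/mol"

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise ValueError(f"unit must be one of {_UNITS}, got {self.unit!r}")
        for name in ("e_complex", "e_host", "e_guest"):
            v = getattr(self, name)
            if v is None or not isinstance(v, (int, float)):
                raise ValueError(f"{name} missing or non-numeric")

    @classmethod
    def from_json(cls, path: str | Path) -> "EnergyLedger":
        raw = json.loads(Path(path).read_text())
        try:
            return cls(
                e_complex=float(raw["e_complex"]),
                e_host=float(raw["e_host"]),
                e_guest=float(raw["e_guest"]),
                unit=raw.get("unit", "kcal/mol"),
            )
        except KeyError as exc:
            raise ValueError(f"energy ledger {path} missing field {exc}") from exc


def delta_e(ledger: EnergyLedger) -> float:
    """ΔE = E_complex − (E_host + E_guest), in kcal/mol."""
    scale = HARTREE_TO_KCAL if ledger.unit == "hartree" else 1.0
    return scale * (ledger.e_complex - (ledger.e_host + ledger.e_guest))


def compare_orientations(
    results: list[tuple[str, float, list]],
) -> dict:
    """Rank inclusion orientations by complexation energy.

    ``results`` is a list of ``(label, ΔE in kcal/mol, hbond list)``. Returns
    a report dict with the orientations sorted ascending by ΔE (ties broken
    by label, so equal energies keep a stable order), all pairwise energy
    differences, and the hydrogen-bond count per orientation.
    """
    if len(results) < 2:
        raise ValueError("need at least two orientations to compare")
    ranked = sorted(results, key=lambda r: (r[1], r[0]))
    report = {
        "ranking": [
            {"label": lab, "delta_e_kcal": de, "n_hbonds": len(hb)}
            for lab, de, hb in ranked
        ],
        "pairwise_differences": [
            {
                "pair": f"{b[0]} - {a[0]}",
                "difference_kcal": round(b[1] - a[1], 10),
            }
            for i, a in enumerate(ranked)
            for b in ranked[i + 1 :]
        ],
    }
    return report
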