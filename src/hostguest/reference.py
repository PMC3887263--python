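"""Reference dataset: ESI-MS peak lists and DFT energetics for β-CD/alendronate.

This module transcribes the published characterization data for the inclusion
complex of alendronate (alendronic acid, AlnH = C4H13NO7P2; administered as
the sodium salt) with β-cyclodextrin (βCD = C42H70O35, seven α-1,4-linked
glucopyranose units): centroid m/z values from the positive- and negative-mode
spectra of the equimolar mixture, the MS/MS neutral-loss ladders, and the
B3LYP/6-31+G* total energies and hydrogen-bond geometries of the two inclusion
orientations.

Intensities were not published; peak lists carry nominal intensities ordered
by the qualitative intensity descriptions ("intense", "small", "very low").

One transcription caveat: the ion at m/z 1,301.378 was originally attributed
to [4βCD + 2AlnH + 3H]3+, which is impossible by exact-mass arithmetic (that
ion sits at m/z 1679.511); the value matches [3βCD + 2AlnH + 3H]3+ within
8 ppm, and that label is recorded here.
"""

from __future__ import annotations

from .energetics import EnergyLedger
from .species import MolecularSpecies

__all__ = [
    "BETA_CD",
    "ALENDRONIC_ACID",
    "GLUCOSE_UNIT",
    "HOST",
    "GUEST",
    "POSITIVE_PEAKS",
    "NEGATIVE_PEAKS",
    "UNASSIGNED_NEGATIVE_MZ",
    "MSMS_POSITIVE_ALN",
    "MSMS_NEGATIVE_ALN",
    "ORIENTATION_LEDGERS",
    "ORIENTATION_HBONDS",
]

BETA_CD = "C42H70O35"
ALENDRONIC_ACID = "C4H13NO7P2"
GLUCOSE_UNIT = "C6H10O5"

HOST = MolecularSpecies.from_string("βCD", BETA_CD)
GUEST = MolecularSpecies.from_string("AlnH", ALENDRONIC_ACID)

# (observed m/z, nominal intensity, expected canonical label)
POSITIVE_PEAKS: list[tuple[float, float, str]] = [
    (250.023, 1000.0, "[AlnH + H]+"),
    (272.005, 900.0, "[AlnH + Na]+"),
    (499.038, 400.0, "[2AlnH + H]+"),
    (590.173, 350.0, "[βCD + 2Na]2+"),
    (649.217, 150.0, "[Glc4 + H]+"),
    (692.697, 120.0, "[βCD + AlnH + 2H]2+"),
    (703.691, 90.0, "[βCD + AlnH + H + Na]2+"),
    (714.681, 80.0, "[βCD + AlnH + 2Na]2+"),
    (725.674, 70.0, "[βCD + AlnH - H + 3Na]2+"),
    (811.267, 110.0, "[Glc5 + H]+"),
    (817.210, 100.0, "[βCD + 2AlnH + 2H]2+"),
    (828.203, 60.0, "[βCD + 2AlnH + H + Na]2+"),
    (839.185, 55.0, "[βCD + 2AlnH + 2Na]2+"),
    (850.182, 50.0, "[βCD + 2AlnH - H + 3Na]2+"),
    (1135.373, 40.0, "[βCD + H]+"),
    (1218.386, 25.0, "[3βCD + AlnH + 3H]3+"),
    (1259.885, 30.0, "[2βCD + AlnH + 2H]2+"),
    (1301.378, 20.0, "[3βCD + 2AlnH + 3H]3+"),
]

NEGATIVE_PEAKS: list[tuple[float, float, str | None]] = [
    (248.007, 1000.0, "[AlnH - H]-"),
    (497.021, 300.0, "[2AlnH - H]-"),
    (690.682, 500.0, "[βCD + AlnH - 2H]2-"),
    (815.189, 120.0, "[βCD + 2AlnH - 2H]2-"),
    (939.691, 90.0, "[βCD + 3AlnH - 2H]2-"),
    (1064.195, 70.0, "[βCD + 4AlnH - 2H]2-"),
    (1179.340, 60.0, None),  # reported but never identified
    (1257.845, 50.0, "[2βCD + AlnH - 2H]2-"),
    (1382.348, 40.0, "[βCD + AlnH - H]-"),
    (1465.354, 10.0, "[3βCD + 4AlnH - 3H]3-"),
]

UNASSIGNED_NEGATIVE_MZ = 1179.340

# MS/MS of protonated alendronic acid, m/z 250.023:
# sequential losses and the observed product m/z values.
MSMS_POSITIVE_ALN: list[tuple[float, tuple[str, ...]]] = [
    (168.041, ("H3PO3",)),
    (150.031, ("H3PO3", "H2O")),
    (86.059, ("H3PO3", "H2O", "HPO2")),
]

# MS/MS of the alendronate anion, m/z 248.007.
MSMS_NEGATIVE_ALN: list[tuple[float, tuple[str, ...]]] = [
    (148.018, ("H3PO3", "H2O")),
]

# B3LYP/6-31+G* total energies (kcal/mol) of the isolated molecules and of the
# complex in each inclusion orientation (1: phosphonate groups entering from
# the wide "top" rim; 2: from the narrow "bottom" rim).
ORIENTATION_LEDGERS: dict[str, EnergyLedger] = {
    "orientation 1": EnergyLedger(
        e_complex=-3_576_293.09,
        e_host=-2_682_715.79,
        e_guest=-893_503.25,
        unit="kcal/mol",
    ),
    "orientation 2": EnergyLedger(
        e_complex=-3_576_279.89,
        e_host=-2_682_715.79,
        e_guest=-893_503.25,
        unit="kcal/mol",
    ),
}

# Intermolecular hydrogen bonds of the optimized complexes:
# (class, H···acceptor length in Å, donor-H···acceptor angle in degrees).
ORIENTATION_HBONDS: dict[str, list[tuple[str, float, float]]] = {
    "orientation 1": [
        ("P=O···H–O", 1.902, 158.76),
        ("P–O···H–O", 1.790, 164.11),
        ("O–H···O", 1.699, 170.42),
        ("O–H···O", 1.751, 159.28),
        ("N···H–O", 1.807, 171.37),
    ],
    "orientation 2": [
        ("O–H···O", 2.073, 169.70),
    ],
}


def fragment_species(max_units: int = 6) -> list[MolecularSpecies]:
    """Glucose-oligomer fragment species (C6H10O5)n, n = 2..max_units.

    These arise from in-source fragmentation of β-cyclodextrin and are
    injected into the candidate list as explicit molecular species rather
    than enumerated as host-guest stoichiometries. n is capped below 7
    because (C6H10O5)7 is isomeric with the intact macrocycle.
    """
    if max_units >= 7:
        raise ValueError("fragment ladder must stop below the intact host (n=7)")
    from .formula import parse_formula

    glc = parse_formula(GLUCOSE_UNIT)
    return [
        MolecularSpecies(f"Glc{n}", n * glc) for n in range(2, max_units + 1)
    ]
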