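"""Synthetic inputs with known ground truth, for end-to-end validation.

Two generators:

* :func:`simulate_spectrum` builds a centroided ESI peak list from a list of
  ion species with relative abundances. Each species contributes its top
  isotopologues at theoretical m/z, perturbed multiplicatively by Gaussian
  jitter of σ ppm (instrument mass error is relative, which is why the
  tolerance gate downstream has a ppm arm). Decoy peaks are drawn uniformly
  over the m/z range and rejected within an exclusion zone of 3σ (at least
  0.02 Da) of any true peak, so truth labels stay unambiguous.

* :func:`plant_hbond_geometry` builds an XYZ-style structure containing
  hydroxyl donor / acceptor fragments arranged to realize requested
  H···acceptor distances and D–H···A angles exactly, each planted bond in
  its own spatial cluster (so donor and acceptor always partition into
  different molecules), plus decoy atoms kept ≥3.5 Å from every planted atom
  so they can neither fake nor break a planted bond.

Both are deterministic under a fixed seed. What they do NOT emulate: peak
shapes and resolution-limited envelope overlap, intensity response factors,
electronic noise, and the conformational context of a real docked complex —
they exercise the bookkeeping of the analysis, not instrument physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .assign import Peak, Spectrum
from .formula import isotope_pattern
from .species import IonSpecies, ion_label, mz_of_ion
from .structure import StructureModel, _build

__all__ = [
    "SpectrumTruth",
    "GeometryTruth",
    "simulate_spectrum",
    "plant_hbond_geometry",
    "evaluate_recovery",
]

OH_BOND = 0.96  # donor O-H covalent length, Å


@dataclass(frozen=True)
class SpectrumTruth:
    """Ground truth for a simulated spectrum."""

    species: tuple[tuple[IonSpecies, float], ...]
    jitter_ppm: float = 3.0
    n_decoys: int = 0
    mz_range: tuple[float, float] = (100.0, 1500.0)
    seed: int = 0
    n_isotopologues: int = 3

    def __post_init__(self) -> None:
        if any(ab <= 0 for _, ab in self.species):
            raise ValueError("species abundances must be positive")
        if self.jitter_ppm < 0:
            raise ValueError("jitter must be non-negative")

    @property
    def polarity(self) -> str:
        signs = {1 if ion.z > 0 else -1 for ion, _ in self.species}
        if len(signs) > 1:
            raise ValueError("species of mixed polarity in one spectrum")
        return "positive" if signs == {1} else "negative"


def simulate_spectrum(t: SpectrumTruth) -> tuple[Spectrum, list[dict]]:
    """Simulate a centroid peak list; returns (spectrum, truth table).

    The truth table has one row per species: the generated (jittered)
    monoisotopic peak m/z, the theoretical m/z, the canonical label, and the
    seed, so recovery can be scored without re-deriving anything.
    """
    rng = np.random.default_rng(t.seed)
    polarity = t.polarity
    peaks: list[Peak] = []
    truth: list[dict] = []
    for ion, abundance in t.species:
        pattern = isotope_pattern(ion.formula, prune_threshold=1e-3, merge_width=0.1)
        zmag = abs(ion.z)
        mono_neutral = pattern.masses[0]
        mono_mz = mz_of_ion(ion)
        row_mz = None
        for (mass, rel), _k in zip(pattern.peaks, range(t.n_isotopologues)):
            theo_mz = mono_mz + (mass - mono_neutral) / zmag
            jitter = rng.normal(0.0, t.jitter_ppm) * 1e-6 if t.jitter_ppm else 0.0
            obs_mz = theo_mz * (1.0 + jitter)
            peaks.append(Peak(obs_mz, abundance * rel * 1000.0))
            if row_mz is None:
                row_mz = obs_mz
        truth.append(
            {
                "mz": row_mz,
                "mz_theoretical": mono_mz,
                "label": ion_label(ion),
                "seed": t.seed,
            }
        )
    exclusion = max(3.0 * t.jitter_ppm * 1e-6 * t.mz_range[1], 0.02)
    true_mzs = np.array([p.mz for p in peaks])
    n_placed = 0
    while n_placed < t.n_decoys:
        mz = float(rng.uniform(*t.mz_range))
        if np.min(np.abs(true_mzs - mz)) < exclusion if len(true_mzs) else False:
            continue
        if any(abs(p.mz - mz) < 1e-5 for p in peaks):
            continue
        peaks.append(Peak(mz, float(rng.uniform(1.0, 50.0))))
        n_placed += 1
    return Spectrum(polarity, tuple(peaks)), truth


@dataclass(frozen=True)
class GeometryTruth:
    """Ground truth for a planted hydrogen-bond structure.

    Planted distances/angles should sit strictly inside (or decoys strictly
    outside) the detection criterion by a clear margin (≥0.05 Å / ≥2°) so
    that recovery is well defined.
    """

    bonds: tuple[tuple[float, float, str], ...]  # (H···A Å, D-H···A deg, class)
    n_decoys: int = 0
    box: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for dist, ang, klass in self.bonds:
            if dist <= OH_BOND or not 0.0 < ang <= 180.0:
                raise ValueError(
                    f"infeasible geometry request d={dist} Å, angle={ang}°"
                )


def _rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (normalized quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _acceptor_fragment(
    klass: str, a_pos: np.ndarray, away: np.ndarray
) -> list[tuple[str, np.ndarray]]:
    """Atoms realizing the requested acceptor chemical environment.

    ``away`` is a unit vector pointing from the acceptor away from the
    planted hydrogen; companion atoms are placed along it so they cannot
    enter the H-bond distance window themselves.
    """
    perp = np.cross(away, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(away, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    if klass.startswith("P=O"):
        # acceptor is the shortest P-O contact of its phosphorus
        p = a_pos + 1.48 * away
        o2 = p + 1.60 * (0.5 * away + math.sqrt(0.75) * perp)
        return [("O", a_pos), ("P", p), ("O", o2)]
    if klass.startswith("P–O") or klass.startswith("P-O"):
        # a shorter companion P-O exists, so the acceptor is a single bond
        p = a_pos + 1.60 * away
        o2 = p + 1.48 * (0.5 * away + math.sqrt(0.75) * perp)
        return [("O", a_pos), ("P", p), ("O", o2)]
    if klass.startswith("N"):
        return [("N", a_pos), ("C", a_pos + 1.47 * away)]
    # conventional hydroxyl acceptor
    return [("O", a_pos), ("C", a_pos + 1.43 * away)]


def plant_hbond_geometry(t: GeometryTruth) -> tuple[StructureModel, list[dict]]:
    """Build a structure with exactly the requested intermolecular H bonds.

    Each planted bond occupies its own cluster on a 12 Å grid: a hydroxyl
    donor (O–H = 0.96 Å) and an acceptor fragment placed to realize the
    requested H···A distance and D–H···A angle, then rigidly rotated by a
    random orientation. Decoy atoms (C/N/O, never H) are scattered in the
    box at least 3.5 Å from all planted atoms.
    """
    rng = np.random.default_rng(t.seed)
    elements: list[str] = []
    coords: list[np.ndarray] = []
    truth: list[dict] = []
    spacing = 12.0
    per_row = max(1, int(t.box // spacing))
    for i, (dist, ang, klass) in enumerate(t.bonds):
        origin = np.array(
            [
                (i % per_row) * spacing,
                ((i // per_row) % per_row) * spacing,
                (i // (per_row * per_row)) * spacing,
            ],
            dtype=float,
        )
        rot = _rotation(rng)
        d_pos = np.zeros(3)
        h_pos = np.array([OH_BOND, 0.0, 0.0])
        theta = math.radians(ang)
        a_dir = np.array([-math.cos(theta), math.sin(theta), 0.0])
        a_pos = h_pos + dist * a_dir
        away = (a_pos - h_pos) / np.linalg.norm(a_pos - h_pos)
        local: list[tuple[str, np.ndarray]] = [("O", d_pos), ("H", h_pos)]
        # anchor the donor hydroxyl on a carbon so it is not a bare water-like O
        local.append(("C", d_pos + 1.43 * np.array([-1.0, 0.0, 0.0])))
        local.extend(_acceptor_fragment(klass, a_pos, away))
        h_index = len(elements) + 1
        a_index = len(elements) + 3
        for elem, pos in local:
            elements.append(elem)
            coords.append(origin + rot @ pos)
        truth.append(
            {
                "hydrogen": h_index,
                "acceptor": a_index,
                "length": dist,
                "angle": ang,
                "class": klass,
                "seed": t.seed,
            }
        )
    planted = np.array(coords) if coords else np.zeros((0, 3))
    n_placed = 0
    guard = 0
    while n_placed < t.n_decoys and guard < 100_000:
        guard += 1
        pos = rng.uniform(-t.box / 2, t.box * 1.2, size=3)
        if len(planted) and np.min(np.linalg.norm(planted - pos, axis=1)) < 3.5:
            continue
        elements.append(str(rng.choice(["C", "N", "O"])))
        coords.append(pos)
        n_placed += 1
    if not elements:
        raise ValueError("nothing to plant: empty truth and no decoys")
    model = _build(elements, np.array(coords), provenance=f"planted(seed={t.seed})")
    return model, truth


def evaluate_recovery(
    truth: list[dict],
    results: list[dict],
    keys: tuple[str, ...],
    value_key: str | None = None,
) -> tuple[float, float, float]:
    """Precision, recall and mean |Δ| of a recovery run against ground truth.

    ``keys`` are the dict fields identifying an item (e.g. ``("label",)`` for
    spectra, ``("hydrogen", "acceptor")`` for H bonds); ``value_key`` names a
    numeric field whose absolute truth-vs-result difference is averaged over
    matched items (0.0 when omitted or nothing matched).
    """
    def ident(row: dict) -> tuple:
        return tuple(row[k] for k in keys)

    truth_map = {ident(r): r for r in truth}
    result_map = {ident(r): r for r in results}
    if len(truth_map) != len(truth) or len(result_map) != len(results):
        raise ValueError("duplicate identifiers within a run")
    matched = set(truth_map) & set(result_map)
    precision = len(matched) / len(result_map) if result_map else 1.0
    recall = len(matched) / len(truth_map) if truth_map else 1.0
    if value_key and matched:
        err = float(
            np.mean(
                [
                    abs(truth_map[m][value_key] - result_map[m][value_key])
                    for m in matched
                ]
            )
        )
    else:
        err = 0.0
    return precision, recall, err
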