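"""Peak-list annotation: adduct assignment, isotope fit, neutral-loss chains.

The assignment model is deliberately simple, matching how high-resolution
ESI-TOF spectra of host-guest mixtures are read in practice: each centroid
peak is compared against the theoretical monoisotopic m/z of every candidate
adduct ion, a match being declared within an absolute (Da) *or* relative
(ppm) tolerance, whichever is wider at that m/z. Candidates for one peak are
ranked by |Δm|; exact ties (e.g. [M+H]+ vs [2M+2H]2+, which share an m/z) are
broken by parsimony — fewer neutral components, then lower charge, then fewer
sodiums, then label. Ranking depends only on m/z; the isotope-profile score
is reported separately so intensity rescaling can never reorder assignments.

Default tolerances are ±0.010 Da and ±25 ppm. The ppm gate is sized to span
the mass-calibration drift seen in the reference mixture spectra, which
grows to ≈23 ppm at high m/z in negative mode while staying below 8 ppm in
positive mode.
"""

from __future__ import annotations

import csv
import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .formula import ElementalFormula, isotope_pattern, monoisotopic_mass, parse_formula
from .species import PROTON_SPACING, IonSpecies, ion_label, mz_of_ion

__all__ = [
    "DEFAULT_TOL_DA",
    "DEFAULT_TOL_PPM",
    "Peak",
    "Spectrum",
    "Assignment",
    "NeutralLoss",
    "LossChain",
    "load_peaklist",
    "assign_peaks",
    "rank_one",
    "unassigned_peaks",
    "nearest_miss",
    "isotope_fit",
    "interpret_msms",
    "assignment_table",
    "STANDARD_LOSSES",
]

logger = logging.getLogger(__name__)

DEFAULT_TOL_DA = 0.010
DEFAULT_TOL_PPM = 25.0


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"non-positive m/z {self.mz}")
        if self.intensity < 0:
            raise ValueError("negative intensity")


@dataclass(frozen=True)
class Spectrum:
    """A centroided peak list of one polarity, sorted by m/z."""

    polarity: str
    peaks: tuple[Peak, ...]
    precursor: IonSpecies | None = None

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")
        object.__setattr__(
            self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mz))
        )
        mzs = [p.mz for p in self.peaks]
        if any(b - a < 1e-6 for a, b in zip(mzs, mzs[1:])):
            raise ValueError("duplicate m/z values (closer than 1e-6)")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])


def load_peaklist(path: str | Path, polarity: str) -> Spectrum:
    """Read a two-column (mz, intensity) CSV peak list, header optional.

    Rows whose fields do not parse as numbers are rejected with a logged
    warning carrying the 1-based line number. Raises on a missing file, on a
    file with no valid rows, and on duplicate m/z values.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or not "".join(row).strip():
                continue
            try:
                mz, inten = float(row[0]), float(row[1]) if len(row) > 1 else 0.0
            except (ValueError, IndexError):
                if lineno == 1:
                    continue  # header
                logger.warning("%s:%d: rejected non-numeric row %r", path, lineno, row)
                continue
            peaks.append(Peak(mz, inten))
    if not peaks:
        raise ValueError(f"{path}: no valid (mz, intensity) rows")
    return Spectrum(polarity, tuple(peaks))


@dataclass(frozen=True)
class Assignment:
    """One candidate explanation of one peak."""

    peak: Peak
    ion: IonSpecies
    theoretical_mz: float
    delta_m: float  # observed - theoretical, Da
    delta_ppm: float
    rank: int
    isotope_score: float | None = None

    @property
    def label(self) -> str:
        return ion_label(self.ion)


def _within(delta: float, mz: float, tol_da: float, tol_ppm: float) -> bool:
    return abs(delta) <= tol_da or abs(delta) / mz * 1e6 <= tol_ppm


def assign_peaks(
    s: Spectrum,
    candidates: list[IonSpecies],
    tol_da: float = DEFAULT_TOL_DA,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> list[Assignment]:
    """Rank all in-tolerance candidates for every peak of the spectrum.

    Returns the concatenated per-peak candidate lists (rank 1 = best).
    Peaks without any in-tolerance candidate contribute nothing here; use
    :func:`unassigned_peaks` / :func:`nearest_miss` to report them.
    """
    if tol_da <= 0 or tol_ppm <= 0:
        raise ValueError("tolerances must be positive")
    sign = 1 if s.polarity == "positive" else -1
    for ion in candidates:
        if ion.z * sign < 0:
            raise ValueError(
                f"candidate {ion_label(ion)} polarity does not match spectrum"
            )
    theo = [(mz_of_ion(ion), ion) for ion in candidates]
    out: list[Assignment] = []
    for peak in s.peaks:
        hits = []
        for t_mz, ion in theo:
            delta = peak.mz - t_mz
            if _within(delta, peak.mz, tol_da, tol_ppm):
                hits.append((t_mz, ion, delta))
        hits.sort(
            key=lambda h: (
                round(abs(h[2]), 9),
                h[1].n_components,
                abs(h[1].z),
                h[1].nNa,
                ion_label(h[1]),
            )
        )
        for rank, (t_mz, ion, delta) in enumerate(hits, start=1):
            out.append(
                Assignment(
                    peak=peak,
                    ion=ion,
                    theoretical_mz=t_mz,
                    delta_m=delta,
                    delta_ppm=delta / peak.mz * 1e6,
                    rank=rank,
                )
            )
    return out


def rank_one(assignments: list[Assignment]) -> dict[float, Assignment]:
    """Best assignment per peak m/z."""
    return {a.peak.mz: a for a in assignments if a.rank == 1}


def unassigned_peaks(s: Spectrum, assignments: list[Assignment]) -> list[Peak]:
    explained = {a.peak.mz for a in assignments}
    return [p for p in s.peaks if p.mz not in explained]


def nearest_miss(
    peak: Peak, candidates: list[IonSpecies]
) -> tuple[IonSpecies, float] | None:
    """Closest candidate to an unassigned peak, with its Δm (Da)."""
    if not candidates:
        return None
    best = min(candidates, key=lambda ion: abs(peak.mz - mz_of_ion(ion)))
    return best, peak.mz - mz_of_ion(best)


def isotope_fit(
    s: Spectrum,
    a: Assignment,
    n_isotopologues: int = 4,
    tol_da: float = DEFAULT_TOL_DA,
) -> float:
    """Cosine similarity between observed and theoretical isotope profiles.

    Intensities are sampled at the isotopologue slots k = 1..n−1 located at
    ``observed_mz + k·1.00336/|z|`` (a missing observed partner contributes
    zero). The monoisotopic anchor slot k = 0 is excluded: it defined the
    match in the first place and would otherwise dominate the cosine, hiding
    a wrong charge-state hypothesis whose slot spacing disagrees with the
    spectrum. Score is in [0, 1]; 1.0 when the hypothesis predicts no visible
    partners and none are observed, 0.0 when predicted partners are absent
    (or vice versa).
    """
    if n_isotopologues < 2:
        raise ValueError("need at least 2 isotopologue slots")
    zmag = abs(a.ion.z)
    spacing = PROTON_SPACING / zmag
    pattern = isotope_pattern(a.ion.formula, prune_threshold=1e-5, merge_width=0.1)
    mono = pattern.masses[0]
    theo = np.zeros(n_isotopologues)
    for m, ab in pattern.peaks:
        k = round((m - mono) / PROTON_SPACING)
        if 0 <= k < n_isotopologues:
            theo[k] += ab
    obs = np.zeros(n_isotopologues)
    mzs = s.mz
    intens = s.intensity
    for k in range(n_isotopologues):
        target = a.peak.mz + k * spacing
        idx = np.argmin(np.abs(mzs - target)) if len(mzs) else None
        if idx is not None and abs(mzs[idx] - target) <= tol_da:
            obs[k] = intens[idx]
    t, o = theo[1:], obs[1:]
    nt, no = float(np.linalg.norm(t)), float(np.linalg.norm(o))
    if nt < 1e-12 and no < 1e-12:
        return 1.0
    if nt < 1e-12 or no < 1e-12:
        return 0.0
    return float(np.dot(t, o) / (nt * no))


@dataclass(frozen=True)
class NeutralLoss:
    """A neutral fragment eliminated during collision-induced dissociation."""

    name: str
    formula: ElementalFormula

    def __post_init__(self) -> None:
        if monoisotopic_mass(self.formula) <= 0:
            raise ValueError(f"neutral loss {self.name!r} has non-positive mass")

    @classmethod
    def from_string(cls, name: str, formula: str | None = None) -> "NeutralLoss":
        return cls(name, parse_formula(formula or name))


#: Losses seen in bisphosphonate / oligosaccharide MS/MS.
STANDARD_LOSSES: list[NeutralLoss] = [
    NeutralLoss.from_string("H3PO3"),
    NeutralLoss.from_string("H2O"),
    NeutralLoss.from_string("HPO2"),
    NeutralLoss.from_string("Glc", "C6H10O5"),
]


@dataclass(frozen=True)
class LossChain:
    """A sequence of neutral losses from a precursor, with the product m/z."""

    losses: tuple[str, ...]
    formula: ElementalFormula
    mz: float

    @property
    def depth(self) -> int:
        return len(self.losses)

    def describe(self) -> str:
        return " ".join(f"-{name}" for name in self.losses) or "(precursor)"


@dataclass(frozen=True)
class MsmsAnnotation:
    peak: Peak
    chain: LossChain
    delta_m: float


def expand_loss_chains(
    precursor: IonSpecies,
    losses: list[NeutralLoss],
    max_depth: int = 4,
) -> list[LossChain]:
    """Breadth-first expansion of sequential single neutral losses.

    Every loss *sequence* is kept (two orderings of the same losses have the
    same product composition but different intermediates, which matters when
    ranking interpretations against observed fragments); a loss that would
    drive an element count negative is pruned silently. Chains come back in
    breadth-first order, the empty chain (the precursor itself) first.
    """
    if abs(precursor.z) != 1:
        raise ValueError("MS/MS interpretation supports singly charged precursors only")
    z = precursor.z
    start = precursor.formula

    def ion_mz(f: ElementalFormula) -> float:
        from .formula import ELECTRON_MASS

        return monoisotopic_mass(f) - z * ELECTRON_MASS

    chains: list[LossChain] = []
    queue: deque[tuple[ElementalFormula, tuple[str, ...]]] = deque([(start, ())])
    while queue:
        f, names = queue.popleft()
        chains.append(LossChain(names, f, ion_mz(f)))
        if len(names) >= max_depth:
            continue
        for loss in losses:
            try:
                queue.append((f - loss.formula, names + (loss.name,)))
            except ValueError:
                continue
    return chains


def interpret_msms(
    precursor: IonSpecies,
    s: Spectrum,
    losses: list[NeutralLoss] | None = None,
    tol_da: float = DEFAULT_TOL_DA,
    max_depth: int = 4,
) -> list[MsmsAnnotation]:
    """Annotate MS/MS product peaks with their best neutral-loss chain.

    Each observed peak is matched against the breadth-first chain expansion.
    Among chains within ``tol_da`` the winner has the smallest |Δm|; exact
    mass ties (e.g. two direct H3PO3 losses vs the H3PO3, H2O, HPO2 sequence
    — identical compositions) are broken in favor of the chain whose
    intermediate fragments are themselves observed in the spectrum, then the
    shorter chain, then expansion order. Peaks with no matching chain are
    omitted. Annotations come back in chain-depth order, then m/z.
    """
    losses = losses if losses is not None else STANDARD_LOSSES
    chains = expand_loss_chains(precursor, losses, max_depth=max_depth)
    observed = np.array([p.mz for p in s.peaks])

    by_prefix = {c.losses: c.mz for c in chains}

    def support(chain: LossChain) -> int:
        """Observed intermediate fragments along the chain (excluding ends)."""
        count = 0
        for k in range(1, chain.depth):
            prefix_mz = by_prefix[chain.losses[:k]]
            if np.any(np.abs(observed - prefix_mz) <= tol_da):
                count += 1
        return count

    out: list[MsmsAnnotation] = []
    for peak in s.peaks:
        hits = [
            (idx, chain, peak.mz - chain.mz)
            for idx, chain in enumerate(chains)
            if abs(peak.mz - chain.mz) <= tol_da
        ]
        if not hits:
            continue
        idx, chain, delta = min(
            hits,
            key=lambda h: (round(abs(h[2]), 9), -support(h[1]), h[1].depth, h[0]),
        )
        out.append(MsmsAnnotation(peak, chain, delta))
    out.sort(key=lambda ann: (ann.chain.depth, ann.peak.mz))
    return out


def assignment_table(
    s: Spectrum,
    assignments: list[Assignment],
    candidates: list[IonSpecies] | None = None,
):
    """Assignment report as a pandas DataFrame (rank-1 rows + unassigned)."""
    import pandas as pd

    rows = []
    best = rank_one(assignments)
    for peak in s.peaks:
        a = best.get(peak.mz)
        if a is not None:
            rows.append(
                {
                    "mz_observed": round(peak.mz, 4),
                    "label": a.label,
                    "mz_theoretical": round(a.theoretical_mz, 4),
                    "delta_mDa": round(a.delta_m * 1e3, 2),
                    "delta_ppm": round(a.delta_ppm, 2),
                    "z": a.ion.z,
                    "isotope_score": a.isotope_score,
                    "rank": a.rank,
                    "status": "assigned",
                }
            )
        else:
            miss = nearest_miss(peak, candidates or [])
            rows.append(
                {
                    "mz_observed": round(peak.mz, 4),
                    "label": ion_label(miss[0]) if miss else None,
                    "mz_theoretical": round(mz_of_ion(miss[0]), 4) if miss else None,
                    "delta_mDa": round(miss[1] * 1e3, 2) if miss else None,
                    "delta_ppm": round(miss[1] / peak.mz * 1e6, 2) if miss else None,
                    "z": None,
                    "isotope_score": None,
                    "rank": None,
                    "status": "unassigned",
                }
            )
    return pd.DataFrame(rows)
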