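"""End-to-end workflows: MS assignment and structure/energetics reports.

These compose the library stages exactly the way the CLI exposes them, and
are the entry points the examples and acceptance checks drive. Every run
serializes its resolved configuration (species, bounds, tolerances, H-bond
criterion, constants-table version, seed) into the output directory so a run
can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import reference
from .assign import (
    DEFAULT_TOL_DA,
    DEFAULT_TOL_PPM,
    Spectrum,
    assign_peaks,
    assignment_table,
    isotope_fit,
    unassigned_peaks,
)
from .energetics import EnergyLedger, compare_orientations, delta_e
from .formula import CONSTANTS_VERSION
from .species import EnumerationBounds, MolecularSpecies, enumerate_ions
from .structure import StructureModel, detect_hbonds, hbond_table

__all__ = ["RunConfig", "run_ms_workflow", "run_structure_workflow"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run."""

    species: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("βCD", reference.BETA_CD),
            ("AlnH", reference.ALENDRONIC_ACID),
        ]
    )
    max_host: int = 4
    max_guest: int = 4
    max_na: int = 4
    max_charge: int = 3
    tol_da: float = DEFAULT_TOL_DA
    tol_ppm: float = DEFAULT_TOL_PPM
    fragment_units: int = 6
    hbond_d_range: tuple[float, float] = (0.8, 2.8)
    hbond_angle_min: float = 120.0
    outdir: str | None = None
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, value)
        cfg.species = [tuple(pair) for pair in cfg.species]
        cfg.hbond_d_range = tuple(cfg.hbond_d_range)
        return cfg

    def molecular_species(self) -> list[MolecularSpecies]:
        return [MolecularSpecies.from_string(n, f) for n, f in self.species]

    def bounds(self, polarity: str) -> EnumerationBounds:
        return EnumerationBounds(
            self.max_host, self.max_guest, self.max_na, self.max_charge, polarity
        )

    def candidates(self, polarity: str):
        """Enumerated host-guest ions plus glucose-fragment adducts."""
        ions = enumerate_ions(self.molecular_species(), self.bounds(polarity))
        if self.fragment_units >= 2:
            frag_bounds = EnumerationBounds(1, 0, 1, 1, polarity)
            for frag in reference.fragment_species(self.fragment_units):
                ions.extend(enumerate_ions([frag], frag_bounds))
        return ions

    def _dump(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        payload = asdict(self)
        payload["constants_version"] = CONSTANTS_VERSION
        (outdir / "run_config.json").write_text(json.dumps(payload, indent=2,
                                                           ensure_ascii=False))


def run_ms_workflow(
    cfg: RunConfig, peaklists: list[Spectrum], score_isotopes: bool = False
) -> dict:
    """Enumerate candidates, assign every peak list, report.

    Returns ``{"tables": [DataFrame, ...], "n_candidates": {...},
    "unassigned": {...}}``; writes TSV/JSON reports into ``cfg.outdir`` when
    set.
    """
    if not peaklists:
        raise ValueError("need at least one peak list")
    tables = []
    n_candidates: dict[str, int] = {}
    unassigned: dict[str, list[float]] = {}
    for idx, spectrum in enumerate(peaklists):
        cands = cfg.candidates(spectrum.polarity)
        n_candidates[f"{idx}:{spectrum.polarity}"] = len(cands)
        assignments = assign_peaks(spectrum, cands, cfg.tol_da, cfg.tol_ppm)
        if score_isotopes:
            from dataclasses import replace

            assignments = [
                replace(a, isotope_score=isotope_fit(spectrum, a, tol_da=cfg.tol_da))
                if a.rank == 1
                else a
                for a in assignments
            ]
        table = assignment_table(spectrum, assignments, cands)
        tables.append(table)
        missed = [p.mz for p in unassigned_peaks(spectrum, assignments)]
        unassigned[f"{idx}:{spectrum.polarity}"] = missed
        logger.info(
            "peak list %d (%s): %d candidates, %d peaks, %d unassigned",
            idx, spectrum.polarity, len(cands), len(spectrum.peaks), len(missed),
        )
    report = {"tables": tables, "n_candidates": n_candidates, "unassigned": unassigned}
    if cfg.outdir:
        outdir = Path(cfg.outdir)
        cfg._dump(outdir)
        for idx, table in enumerate(tables):
            table.to_csv(outdir / f"assignments_{idx}.tsv", sep="\t", index=False)
        (outdir / "unassigned.json").write_text(json.dumps(unassigned, indent=2))
    return report


def run_structure_workflow(
    cfg: RunConfig,
    structures: list[tuple[str, StructureModel | None]],
    ledgers: list[tuple[str, EnergyLedger]],
) -> dict:
    """Per-orientation H-bond tables and ΔE, plus a cross-orientation ranking.

    ``structures`` may carry ``None`` models for orientations whose optimized
    coordinates are unavailable (published geometries often are); those
    contribute an empty bond list but still enter the energy comparison.
    """
    if not ledgers:
        raise ValueError("need at least one energy ledger")
    struct_map = dict(structures)
    per_orientation = []
    for label, ledger in ledgers:
        model = struct_map.get(label)
        bonds = (
            detect_hbonds(model, cfg.hbond_d_range, cfg.hbond_angle_min)
            if model is not None
            else []
        )
        per_orientation.append((label, delta_e(ledger), bonds))
    report: dict = {
        "orientations": [
            {
                "label": lab,
                "delta_e_kcal": round(de, 2),
                "n_hbonds": len(bonds),
                "hbonds": hbond_table(struct_map[lab], bonds).to_dict("records")
                if struct_map.get(lab) is not None
                else [],
            }
            for lab, de, bonds in per_orientation
        ]
    }
    if len(per_orientation) >= 2:
        report["comparison"] = compare_orientations(per_orientation)
    if cfg.outdir:
        outdir = Path(cfg.outdir)
        cfg._dump(outdir)
        (outdir / "energetics.json").write_text(
            json.dumps(report, indent=2, ensure_ascii=False)
        )
    return report
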