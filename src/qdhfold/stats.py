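"""Ensemble statistics: restraint violations, covalent-geometry
deviations, and pairwise heavy-atom RMSD over named atom selections.

These mirror the categories conventionally reported for NMR ensembles:
the number of distance restraints violated by more than 0.2 A (mean +/- sd
over conformers), RMS deviations of bonds/angles/impropers from the ideal
template geometry, and pairwise Kabsch RMSD over the selected low-energy
structures for a core selection ("G-tetrad core" = heavy atoms of
G-tetrad member residues) and for all heavy atoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable

import numpy as np

from . import chem
from .chem import Conformer, Ensemble, MolecularTemplate
from .restraints import DistanceRestraint
from .topology import QDHTopology

__all__ = [
    "StatReport",
    "kabsch_rmsd",
    "pairwise_rmsd",
    "violation_count",
    "geometry_deviations",
    "tetrad_core_selection",
    "heavy_atom_selection",
    "ensemble_report",
]

AtomPredicate = Callable[[int, str, str], bool]  # (residue, atom name, element)


def heavy_atom_selection(residues: set[int] | None = None) -> AtomPredicate:
    """All non-hydrogen atoms, optionally limited to ``residues``."""

    def pred(res: int, name: str, element: str) -> bool:
        return element != "H" and (residues is None or res in residues)

    return pred


def tetrad_core_selection(t: QDHTopology) -> AtomPredicate:
    """Heavy atoms of all G-tetrad member residues (G.C.G.C excluded)."""
    members = {m for tet in t.g_tetrads for m in tet.members}
    return heavy_atom_selection(members)


def _select(conf: Conformer, selection: AtomPredicate) -> np.ndarray:
    mask = np.array(
        [
            selection(int(r), str(a), str(e))
            for r, a, e in zip(conf.res_index, conf.atom_name, conf.element)
        ],
        bool,
    )
    return conf.coord[mask]


def kabsch_rmsd(a: Conformer, b: Conformer, selection: AtomPredicate | None = None) -> float:
    """Minimal RMSD (A) after optimal rigid superposition (rotation +
    translation, no reflection) over the matched atom selections."""
    if selection is None:
        selection = heavy_atom_selection()
    pa, pb = _select(a, selection), _select(b, selection)
    if pa.shape != pb.shape:
        raise ValueError(
            f"selection sizes differ: {pa.shape[0]} vs {pb.shape[0]} atoms"
        )
    if len(pa) == 0:
        raise ValueError("empty selection")
    r, t = chem.kabsch_transform(pa, pb)
    diff = pa @ r.T + t - pb
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def pairwise_rmsd(
    e: Ensemble, selection: AtomPredicate | None = None
) -> tuple[float, float]:
    """Mean and population sd of Kabsch RMSD over all unordered pairs of
    flagged conformers."""
    flagged = e.flagged if any(e.selected) else e.conformers
    if len(flagged) < 2:
        raise ValueError("need at least 2 conformers for pairwise RMSD")
    vals = [
        kabsch_rmsd(a, b, selection) for a, b in combinations(flagged, 2)
    ]
    return float(np.mean(vals)), float(np.std(vals))


def violation_count(
    conf: Conformer,
    restraints: list[DistanceRestraint],
    threshold: float = 0.2,
) -> int:
    """Number of distance restraints violated by strictly more than
    ``threshold`` A beyond either flat-bottom bound."""
    n = 0
    for r in restraints:
        d = float(
            np.linalg.norm(conf.position(*r.atom_a) - conf.position(*r.atom_b))
        )
        if d > r.upper + threshold or d < r.lower - threshold:
            n += 1
    return n


def geometry_deviations(
    conf: Conformer, template: MolecularTemplate | None = None
) -> tuple[float, float, float]:
    """RMS deviations from ideal covalent geometry: (bond A, angle deg,
    improper deg)."""
    bonds, angles, impropers = chem.chain_terms(conf, template)
    x = conf.coord
    bd = []
    for i, j, ideal in bonds:
        bd.append(np.linalg.norm(x[i] - x[j]) - ideal)
    ad = []
    for i, j, k, ideal in angles:
        u, v = x[i] - x[j], x[k] - x[j]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        ad.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))) - ideal)
    idv = []
    for c, i, j, k, ideal in impropers:
        phi = chem.dihedral_deg(x[i], x[c], x[j], x[k])
        idv.append(((phi - ideal + 180.0) % 360.0) - 180.0)

    def rms(v):
        return float(np.sqrt(np.mean(np.square(v)))) if len(v) else 0.0

    return rms(bd), rms(ad), rms(idv)


@dataclass
class StatReport:
    """Ensemble statistics over the flagged conformers (mean +/- population sd)."""

    violations_mean: float
    violations_sd: float
    bond_dev_mean: float
    bond_dev_sd: float
    angle_dev_mean: float
    angle_dev_sd: float
    improper_dev_mean: float
    improper_dev_sd: float
    rmsd_core_mean: float
    rmsd_core_sd: float
    rmsd_all_heavy_mean: float
    rmsd_all_heavy_sd: float

    def to_text(self) -> str:
        f = lambda m, s: f"{m:.3f} ± {s:.3f}"
        return "\n".join(
            [
                "B. Structure Statistics",
                "NOE violations",
                f"  Number (>0.2 A)\t{f(self.violations_mean, self.violations_sd)}",
                "Deviations from the ideal geometry",
                f"  Bond lengths (A)\t{f(self.bond_dev_mean, self.bond_dev_sd)}",
                f"  Bond angles (deg)\t{f(self.angle_dev_mean, self.angle_dev_sd)}",
                f"  Impropers (deg)\t{f(self.improper_dev_mean, self.improper_dev_sd)}",
                "Pairwise heavy atom RMSD value (A)",
                f"  G-tetrad core\t{f(self.rmsd_core_mean, self.rmsd_core_sd)}",
                f"  All heavy atom\t{f(self.rmsd_all_heavy_mean, self.rmsd_all_heavy_sd)}",
            ]
        )

    def to_tsv(self) -> str:
        rows = [
            ("noe_violations_gt_0.2A", self.violations_mean, self.violations_sd),
            ("bond_dev_A", self.bond_dev_mean, self.bond_dev_sd),
            ("angle_dev_deg", self.angle_dev_mean, self.angle_dev_sd),
            ("improper_dev_deg", self.improper_dev_mean, self.improper_dev_sd),
            ("rmsd_core_A", self.rmsd_core_mean, self.rmsd_core_sd),
            ("rmsd_all_heavy_A", self.rmsd_all_heavy_mean, self.rmsd_all_heavy_sd),
        ]
        out = ["statistic\tmean\tsd"]
        out += [f"{n}\t{m:.4f}\t{s:.4f}" for n, m, s in rows]
        return "\n".join(out) + "\n"


def ensemble_report(
    e: Ensemble,
    t: QDHTopology,
    restraints: list[DistanceRestraint],
    template: MolecularTemplate | None = None,
    threshold: float = 0.2,
) -> StatReport:
    """Full Table-of-statistics style report over the flagged conformers."""
    flagged = e.flagged if any(e.selected) else e.conformers
    if not flagged:
        raise ValueError("empty ensemble")
    viols = np.array(
        [violation_count(c, restraints, threshold) for c in flagged], float
    )
    devs = np.array([geometry_deviations(c, template) for c in flagged])
    core_m, core_s = pairwise_rmsd(e, tetrad_core_selection(t))
    all_m, all_s = pairwise_rmsd(e, heavy_atom_selection())
    return StatReport(
        float(viols.mean()), float(viols.std()),
        float(devs[:, 0].mean()), float(devs[:, 0].std()),
        float(devs[:, 1].mean()), float(devs[:, 1].std()),
        float(devs[:, 2].mean()), float(devs[:, 2].std()),
        core_m, core_s, all_m, all_s,
    )
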