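"""Molecular templates and all-atom chain construction for DNA.

Ideal nucleotide geometry (atom inventories, bonds, reference coordinates
for DA/DC/DG/DT) comes from the chemical component dictionary bundled with
biotite.  From the reference coordinates we derive ideal bond lengths,
bond angles and improper-torsion values; these define both the covalent
force field of the annealing engine and the "ideal geometry" that ensemble
statistics measure deviations against.

Conventions
-----------
* Residues are named DA/DC/DG/DT (wwPDB) and numbered 1-based.
* Every residue carries a 5'-phosphate (OP3 and its proton are dropped,
  as are HOP2 and the O3' hydroxyl proton except on the 3'-terminal
  residue).
* Chains are built 5'->3'; the inter-residue O3'-P linkage uses a fixed
  ideal bond length and the two flanking ideal angles below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

__all__ = [
    "Conformer",
    "Ensemble",
    "MolecularTemplate",
    "standard_template",
    "build_chain",
    "kabsch_transform",
]

BASE_TO_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
RESNAME_TO_BASE = {v: k for k, v in BASE_TO_RESNAME.items()}

ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974}
VDW_RADIUS = {"H": 1.00, "C": 1.50, "N": 1.40, "O": 1.30, "P": 1.70}

# inter-residue O3'(i)-P(i+1) linkage ideals
LINK_BOND_O3_P = 1.607  # Angstrom
LINK_ANGLE_C3_O3_P = 119.7  # degrees
LINK_ANGLE_O3_P_O5 = 104.0  # degrees

_DROP_ALWAYS = {"OP3", "HOP3", "HOP2"}

# Amino-proton naming convention: Hx1 is the proton cis to the flanking
# ring nitrogen of the Watson-Crick edge (the hydrogen-bonding one);
# reference ideal coordinates that place it trans are relabelled.
# (ring reference atom, amino carbon, amino nitrogen, H1, H2)
_AMINO_CIS = {
    "DG": ("N1", "C2", "N2", "H21", "H22"),
    "DC": ("N3", "C4", "N4", "H41", "H42"),
    "DA": ("N1", "C6", "N6", "H61", "H62"),
}


@dataclass
class Conformer:
    """All-atom Cartesian model of one DNA chain.

    Parallel per-atom arrays; ``coord`` is (n_atoms, 3) in Angstrom.
    ``energy`` is filled once the conformer has been scored
    (kcal/mol, covalent + restraint terms).
    """

    res_index: np.ndarray  # int, 1-based
    res_name: np.ndarray  # str, DA/DC/DG/DT
    atom_name: np.ndarray  # str
    element: np.ndarray  # str
    coord: np.ndarray  # (n, 3) float
    energy: float | None = None

    def __post_init__(self):
        self._index: dict[tuple[int, str], int] = {
            (int(r), str(a)): i
            for i, (r, a) in enumerate(zip(self.res_index, self.atom_name))
        }

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def n_residues(self) -> int:
        return int(self.res_index.max()) if self.n_atoms else 0

    @property
    def sequence(self) -> str:
        seen: dict[int, str] = {}
        for r, n in zip(self.res_index, self.res_name):
            seen.setdefault(int(r), RESNAME_TO_BASE[str(n)])
        return "".join(seen[i] for i in sorted(seen))

    def atom_index(self, residue: int, atom: str) -> int:
        try:
            return self._index[(residue, atom)]
        except KeyError:
            raise KeyError(f"atom {atom!r} of residue {residue} not in conformer") from None

    def has_atom(self, residue: int, atom: str) -> bool:
        return (residue, atom) in self._index

    def position(self, residue: int, atom: str) -> np.ndarray:
        return self.coord[self.atom_index(residue, atom)]

    def with_coord(self, coord: np.ndarray, energy: float | None = None) -> "Conformer":
        if not np.all(np.isfinite(coord)):
            raise ValueError("non-finite coordinates")
        return Conformer(
            self.res_index, self.res_name, self.atom_name, self.element,
            np.asarray(coord, float).reshape(-1, 3).copy(), energy,
        )

    def copy(self) -> "Conformer":
        return self.with_coord(self.coord.copy(), self.energy)


@dataclass
class Ensemble:
    """Ordered conformers with energies; ``selected`` flags the low-energy
    subset retained for reporting (the "10 lowest-energy structures")."""

    conformers: list[Conformer]
    selected: list[bool] = field(default_factory=list)

    def __post_init__(self):
        if not self.selected:
            self.selected = [False] * len(self.conformers)
        if len(self.selected) != len(self.conformers):
            raise ValueError("selected mask length mismatch")

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def energies(self) -> np.ndarray:
        return np.array([c.energy if c.energy is not None else np.nan
                         for c in self.conformers])

    @property
    def flagged(self) -> list[Conformer]:
        return [c for c, s in zip(self.conformers, self.selected) if s]

    def select_lowest(self, n: int) -> "Ensemble":
        order = np.argsort(self.energies, kind="stable")
        mask = [False] * len(self)
        for i in order[:n]:
            mask[int(i)] = True
        return Ensemble(self.conformers, mask)


@dataclass(frozen=True)
class ResidueTemplate:
    name: str  # DG etc.
    atoms: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray  # ideal reference coordinates, (n, 3)
    bonds: tuple[tuple[str, str, float], ...]  # (a, b, ideal length)
    angles: tuple[tuple[str, str, str, float], ...]  # (a, b, c, ideal deg)
    impropers: tuple[tuple[str, str, str, str, float], ...]  # central atom first

    def atom_pos(self, name: str) -> np.ndarray:
        return self.coords[self.atoms.index(name)]


@dataclass(frozen=True)
class MolecularTemplate:
    """Per-residue-type geometry plus the inter-residue linkage ideals."""

    residues: dict[str, ResidueTemplate]
    link_bond: float = LINK_BOND_O3_P
    link_angle_c3_o3_p: float = LINK_ANGLE_C3_O3_P
    link_angle_o3_p_o5: float = LINK_ANGLE_O3_P_O5

    def for_base(self, base: str) -> ResidueTemplate:
        try:
            return self.residues[BASE_TO_RESNAME[base]]
        except KeyError:
            raise ValueError(f"unknown base {base!r}; expected one of ACGT") from None


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x, y = np.dot(n1, n2), np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def _residue_template(resname: str, drop_ho3: bool) -> ResidueTemplate:
    import biotite.structure.info as info

    ref = info.residue(resname)
    drop = set(_DROP_ALWAYS)
    if drop_ho3:
        drop.add("HO3'")
    keep = [i for i, n in enumerate(ref.atom_name) if n not in drop]
    names = list(str(ref.atom_name[i]) for i in keep)
    base_res = resname.rstrip("3")
    if base_res in _AMINO_CIS:
        ref_at, c_at, n_at, h1, h2 = _AMINO_CIS[base_res]
        idx = {str(ref.atom_name[i]): i for i in range(ref.array_length())}
        tor = dihedral_deg(
            ref.coord[idx[ref_at]], ref.coord[idx[c_at]],
            ref.coord[idx[n_at]], ref.coord[idx[h1]],
        )
        if abs(tor) > 90.0:  # h1 placed trans in the reference: relabel
            names = [h2 if n == h1 else (h1 if n == h2 else n) for n in names]
    names = tuple(names)
    elements = tuple(str(ref.element[i]).capitalize() for i in keep)
    coords = np.array([ref.coord[i] for i in keep], float)
    pos = {n: coords[i] for i, n in enumerate(names)}

    bond_pairs: list[tuple[str, str]] = []
    adj: dict[str, list[str]] = {n: [] for n in names}
    for i, j, _ in ref.bonds.as_array():
        a, b = str(ref.atom_name[i]), str(ref.atom_name[j])
        if a in pos and b in pos:
            bond_pairs.append((a, b))
            adj[a].append(b)
            adj[b].append(a)
    # deterministic neighbor order: CCD atom order
    order = {n: i for i, n in enumerate(names)}
    for n in adj:
        adj[n].sort(key=lambda x: order[x])

    bonds = tuple(
        (a, b, float(np.linalg.norm(pos[a] - pos[b]))) for a, b in bond_pairs
    )
    angles = []
    impropers = []
    for center, nbrs in adj.items():
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                angles.append(
                    (nbrs[i], center, nbrs[j],
                     _angle_deg(pos[nbrs[i]], pos[center], pos[nbrs[j]]))
                )
        if len(nbrs) >= 3:
            # improper torsion n0-center-n1-n2: near 0/180 for planar
            # centers, signed for chiral sugar carbons (records handedness)
            n0, n1, n2 = nbrs[0], nbrs[1], nbrs[2]
            val = dihedral_deg(pos[n0], pos[center], pos[n1], pos[n2])
            impropers.append((center, n0, n1, n2, val))
    return ResidueTemplate(
        resname, names, elements, coords, bonds, tuple(angles), tuple(impropers)
    )


@lru_cache(maxsize=None)
def standard_template() -> MolecularTemplate:
    """The standard DNA template (DA/DC/DG/DT from the bundled CCD)."""
    residues = {}
    for resname in ("DA", "DC", "DG", "DT"):
        residues[resname] = _residue_template(resname, drop_ho3=True)
        residues[resname + "3"] = _residue_template(resname, drop_ho3=False)
    return MolecularTemplate(residues)


def _terminal_name(resname: str) -> str:
    """Internal key for the 3'-terminal variant (keeps HO3')."""
    return resname + "3"


def _nerf_place(a, b, c, bond: float, angle_deg_: float, torsion_deg: float):
    """Place atom D given A-B-C, |CD|, angle(BCD) and torsion(ABCD)."""
    ang = np.radians(angle_deg_)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch_transform(mobile: np.ndarray, target: np.ndarray):
    """Optimal rotation R and translation t minimising |R@mobile+t-target|
    (proper rotation only, no reflection)."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    r = vt.T @ diag @ u.T
    return r, tc - r @ mc


def build_chain(sequence: str, template: MolecularTemplate | None = None) -> Conformer:
    """Deterministic extended all-atom chain with ideal covalent geometry.

    Each residue is placed as a rigid copy of its template geometry; the
    O3'(i)-P(i+1) linkage gets the ideal link bond/angles with extended
    (180 deg) junction torsions.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if template is None:
        template = standard_template()
    for b in sequence:
        if b not in BASE_TO_RESNAME:
            raise ValueError(f"unknown base {b!r} in sequence")

    res_index, res_name, atom_name, element, coords = [], [], [], [], []
    prev: dict[str, np.ndarray] = {}
    for i, base in enumerate(sequence):
        resname = BASE_TO_RESNAME[base]
        key = _terminal_name(resname) if i == len(sequence) - 1 else resname
        rt = template.residues[key]
        if i == 0:
            placed = rt.coords.copy()
        else:
            # NeRF the junction: P, then O5', then C5', then rigid-fit
            d_p_o5 = float(np.linalg.norm(rt.atom_pos("P") - rt.atom_pos("O5'")))
            d_o5_c5 = float(np.linalg.norm(rt.atom_pos("O5'") - rt.atom_pos("C5'")))
            ang_p_o5_c5 = _angle_deg(
                rt.atom_pos("P"), rt.atom_pos("O5'"), rt.atom_pos("C5'")
            )
            p = _nerf_place(
                prev["C4'"], prev["C3'"], prev["O3'"],
                template.link_bond, template.link_angle_c3_o3_p, 180.0,
            )
            o5 = _nerf_place(
                prev["C3'"], prev["O3'"], p,
                d_p_o5, template.link_angle_o3_p_o5, 180.0,
            )
            # alpha-like torsion of 120 deg keeps the phosphate oxygens
            # clear of the preceding O3' while staying extended
            c5 = _nerf_place(prev["O3'"], p, o5, d_o5_c5, ang_p_o5_c5, 120.0)
            mobile = np.array(
                [rt.atom_pos("P"), rt.atom_pos("O5'"), rt.atom_pos("C5'")]
            )
            r, t = kabsch_transform(mobile, np.array([p, o5, c5]))
            placed = rt.coords @ r.T + t
        for n, e, xyz in zip(rt.atoms, rt.elements, placed):
            res_index.append(i + 1)
            res_name.append(resname)
            atom_name.append(n)
            element.append(e)
            coords.append(xyz)
        prev = {n: placed[k] for k, n in enumerate(rt.atoms)}

    return Conformer(
        np.array(res_index, int),
        np.array(res_name, dtype=object),
        np.array(atom_name, dtype=object),
        np.array(element, dtype=object),
        np.array(coords, float),
    )


def chain_terms(conf: Conformer, template: MolecularTemplate | None = None):
    """Covalent term lists for a chain: (bonds, angles, impropers) with
    atom indices into ``conf`` and ideal values.

    Bonds: (i, j, length A).  Angles: (i, j, k, deg) with j central.
    Impropers: (c, i, j, k, deg) torsion i-c-j-k with c the central atom.
    Inter-residue linkage contributes the O3'-P bond and its two flanking
    angles; phosphate impropers and the remaining junction angles are
    intentionally left unrestrained.
    """
    if template is None:
        template = standard_template()
    seq = conf.sequence
    bonds, angles, impropers = [], [], []
    for ri, base in enumerate(seq, start=1):
        resname = BASE_TO_RESNAME[base]
        key = _terminal_name(resname) if ri == len(seq) else resname
        rt = template.residues[key]
        for a, b, ideal in rt.bonds:
            bonds.append((conf.atom_index(ri, a), conf.atom_index(ri, b), ideal))
        for a, b, c, ideal in rt.angles:
            angles.append(
                (conf.atom_index(ri, a), conf.atom_index(ri, b),
                 conf.atom_index(ri, c), ideal)
            )
        for c, a, b, d, ideal in rt.impropers:
            impropers.append(
                (conf.atom_index(ri, c), conf.atom_index(ri, a),
                 conf.atom_index(ri, b), conf.atom_index(ri, d), ideal)
            )
        if ri < len(seq):
            o3 = conf.atom_index(ri, "O3'")
            c3 = conf.atom_index(ri, "C3'")
            p = conf.atom_index(ri + 1, "P")
            o5 = conf.atom_index(ri + 1, "O5'")
            bonds.append((o3, p, template.link_bond))
            angles.append((c3, o3, p, template.link_angle_c3_o3_p))
            angles.append((o3, p, o5, template.link_angle_o3_p_o5))
    return bonds, angles, impropers
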