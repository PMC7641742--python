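"""Synthetic ground-truth inputs for every pipeline stage.

This module generates the inputs the analysis needs -- idealized QDH
coordinates, classed NOE peak lists, CD spectra and melting curves -- from
known ground truth, so that restraint generation, the annealing engine and
the CD analyses can all be exercised and validated without any external
data.

The idealized coordinate builder places tetrads as stacked planar units
whose in-plane geometry is solved so the canonical hydrogen-bond
distances (Hoogsteen around a G-tetrad, Watson-Crick within G.C pairs)
are met, stacks the duplex stem coaxially, interpolates loop residues,
and finally regularises the assembly by minimising the covalent force
field under the fold's own hydrogen-bond/dihedral/planarity restraints.
The result is a physically consistent all-atom reference that satisfies
the restraints it will later be asked to generate -- which is all a
ground-truth structure needs; it is *synthetic*, not a deposited
experimental model.

CD components are parametric Gaussian-band mock-ups qualitatively
matching the forms' signatures (hybrid-type: positive ~265 nm with a
~290 nm shoulder; antiparallel: positive ~290 nm, negative ~255 nm);
only their linear independence matters for decomposition tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from . import chem, engine
from .cd_analysis import Baseline, CDSpectrum, MeltCurve
from .chem import Conformer
from .restraints import (
    HOOGSTEEN_DISTANCES,
    WATSON_CRICK_DISTANCES,
    dihedral_restraints,
    hbond_restraints,
    planarity_restraints,
)
from .topology import QDHTopology, validate_topology

__all__ = [
    "IdealGeometryParams",
    "NoiseModel",
    "build_idealized_coords",
    "simulate_noe_peaks",
    "simulate_cd_mixture",
    "simulate_melting_curve",
    "form1_like_spectrum",
    "form2_like_spectrum",
    "two_state_theta",
]

GAS_CONSTANT = 0.0019872041  # kcal/mol/K

EXCHANGEABLE_PROTONS = {
    "H1", "H3", "H21", "H22", "H41", "H42", "H61", "H62", "HO3'", "HO5'",
}

BASE_ATOMS = {
    "G": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4",
          "H8", "H1", "H21", "H22"),
    "A": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4",
          "H8", "H2", "H61", "H62"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6",
          "H41", "H42", "H5", "H6"),
    "T": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6",
          "H3", "H71", "H72", "H73", "H6"),
}
GLYCOSIDIC_N = {"G": "N9", "A": "N9", "C": "N1", "T": "N1"}


@dataclass(frozen=True)
class IdealGeometryParams:
    """Geometry of the idealized reference: stacked planar tetrads with a
    B-form-like coaxial stem."""

    rise: float = 3.4  # A between stacked layers
    twist: float = 30.0  # deg between tetrad layers
    stem_twist: float = 36.0  # deg between duplex base-pair layers
    loop_bulge: float = 9.0  # A radial offset for interpolated loop residues
    regularize_iter: int = 8000
    seed: int = 0

    def __post_init__(self):
        if self.rise <= 0:
            raise ValueError("rise must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Peak-list noise: distance jitter before class quantisation,
    class-boundary distances (A), and a false-negative drop rate."""

    distance_jitter_sd: float = 0.1
    class_boundaries: tuple[float, float] = (3.0, 4.5)
    exch_class_boundaries: tuple[float, float] = (4.5, 5.5)
    min_distance: float = 2.0
    exch_min_distance: float = 3.0
    false_negative_rate: float = 0.0
    stereospecific_methylene: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.false_negative_rate <= 1:
            raise ValueError("false_negative_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# Planar unit layouts

def _flat_base(base: str) -> dict[str, np.ndarray]:
    """Base atoms of the template residue, centered and rotated into z=0."""
    rt = chem.standard_template().for_base(base)
    names = [a for a in BASE_ATOMS[base] if a in rt.atoms]
    pts = np.array([rt.atom_pos(a) for a in names])
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center)
    rot = vt  # rows: principal axes; third row = plane normal
    flat = (pts - center) @ rot.T
    return {n: p for n, p in zip(names, flat)}


def _rz(deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _apply2d(pts: np.ndarray, tx: float, ty: float, rot_deg: float,
             flip: bool = False) -> np.ndarray:
    out = pts.copy()
    if flip:  # flip about the x-axis (base upside down, stays planar)
        out = out * np.array([1.0, -1.0, -1.0])
    out = out @ _rz(rot_deg).T
    out[:, 0] += tx
    out[:, 1] += ty
    return out


@lru_cache(maxsize=None)
def _g_tetrad_layout(direction: int = 1) -> dict[str, np.ndarray]:
    """In-plane placement of one guanine of a fourfold-symmetric G-tetrad.

    ``direction`` +1: the Hoogsteen acceptor sits 90 deg anticlockwise of
    the donor; -1: clockwise.  Solved so the four canonical donor->acceptor
    distances are met.  Returns the placed base-atom map of member 0;
    member k is the 90*k deg rotation.
    """
    base = _flat_base("G")
    names = list(base)
    pts0 = np.array([base[n] for n in names])
    targets = [(a, b, d) for a, b, d, _ in HOOGSTEEN_DISTANCES]

    def residuals(params, flip):
        tx, ty, rot = params
        placed = _apply2d(pts0, tx, ty, rot, flip)
        neighbor = placed @ _rz(direction * 90.0).T
        p = {n: placed[i] for i, n in enumerate(names)}
        q = {n: neighbor[i] for i, n in enumerate(names)}
        return [np.linalg.norm(p[a] - q[b]) - d for a, b, d in targets]

    best = None
    for flip in (False, True):
        for rot0 in range(0, 360, 30):
            for r0 in (3.0, 4.5, 6.0):
                sol = least_squares(
                    residuals, x0=[r0, 0.0, float(rot0)], args=(flip,),
                    method="lm", max_nfev=2000,
                )
                if best is None or sol.cost < best[0]:
                    best = (sol.cost, sol.x, flip)
    cost, (tx, ty, rot), flip = best
    placed = _apply2d(pts0, tx, ty, rot, flip)
    return {n: placed[i] for i, n in enumerate(names)}


@lru_cache(maxsize=None)
def _wc_pair_layout() -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """In-plane Watson-Crick G.C pair solved for the six canonical
    hydrogen-bond distances; centered at the origin."""
    g = _flat_base("G")
    c = _flat_base("C")
    gnames, cnames = list(g), list(c)
    gpts = np.array([g[n] for n in gnames])
    cpts0 = np.array([c[n] for n in cnames])
    targets = [(a, b, d) for a, b, d, _ in WATSON_CRICK_DISTANCES]

    def residuals(params, flip):
        tx, ty, rot = params
        placed = _apply2d(cpts0, tx, ty, rot, flip)
        q = {n: placed[i] for i, n in enumerate(cnames)}
        return [np.linalg.norm(g[a] - q[b]) - d for a, b, d in targets]

    best = None
    for flip in (False, True):
        for rot0 in range(0, 360, 30):
            for (x0, y0) in ((6.0, 0.0), (-6.0, 0.0), (0.0, 6.0), (0.0, -6.0)):
                sol = least_squares(
                    residuals, x0=[x0, y0, float(rot0)], args=(flip,),
                    method="lm", max_nfev=2000,
                )
                if best is None or sol.cost < best[0]:
                    best = (sol.cost, sol.x, flip)
    cost, (tx, ty, rot), flip = best
    cpts = _apply2d(cpts0, tx, ty, rot, flip)
    cmap = {n: cpts[i] for i, n in enumerate(cnames)}
    # center the pair
    allpts = np.vstack([gpts, cpts])
    shift = allpts.mean(axis=0)
    return (
        {n: g[n] - shift for n in gnames},
        {n: cmap[n] - shift for n in cnames},
    )


# ---------------------------------------------------------------------------
# Layer stacking

def _stack_order(t: QDHTopology) -> list:
    """Order tetrad layers so sequence-adjacent members stack in columns
    and any G.C.G.C tetrad ends up on the stem side (last)."""
    from itertools import permutations

    g_layers = list(t.g_tetrads)
    gcgc = list(t.gcgc_tetrads)

    def adjacency(a, b) -> int:
        return sum(
            1 for m in a.members for n in b.members if abs(m - n) == 1
        )

    if len(g_layers) > 1:
        best = None
        for perm in permutations(range(len(g_layers))):
            score = sum(
                adjacency(g_layers[perm[i]], g_layers[perm[i + 1]])
                for i in range(len(perm) - 1)
            )
            if gcgc:
                score += adjacency(g_layers[perm[-1]], gcgc[0])
            if best is None or score > best[0]:
                best = (score, perm)
        g_layers = [g_layers[i] for i in best[1]]
    return g_layers + gcgc


def _assign_positions(layers: list, t: QDHTopology) -> dict[int, int]:
    """Assign each G-tetrad member an angular slot (0..3 -> 0/90/180/270
    deg) so that sequence-adjacent residues in consecutive layers share a
    slot.  The first layer takes its listed order; later layers inherit
    through adjacency."""
    slots: dict[int, int] = {}
    prev = None
    for layer in layers:
        if layer.kind != "G-tetrad":
            continue
        if prev is None:
            for i, m in enumerate(layer.members):
                slots[m] = i
        else:
            for m in layer.members:
                anchor = [n for n in prev.members if abs(m - n) == 1]
                if anchor:
                    slots[m] = slots[anchor[0]]
            # fall back for unanchored members: keep any free slot
            used = {slots[m] for m in layer.members if m in slots}
            free = [s for s in range(4) if s not in used]
            for m in layer.members:
                if m not in slots:
                    slots[m] = free.pop(0)
        prev = layer
    return slots


def _chi_of(residue_pts: dict[str, np.ndarray], base: str) -> float:
    n = GLYCOSIDIC_N[base]
    c_atom = "C4" if n == "N9" else "C2"
    return chem.dihedral_deg(
        residue_pts["O4'"], residue_pts["C1'"], residue_pts[n], residue_pts[c_atom]
    )


def _place_residue(
    base: str,
    target_base_atoms: dict[str, np.ndarray],
    chi_target: float | None,
    terminal: bool,
) -> tuple[list[str], np.ndarray]:
    """Rigid-fit the full template residue onto placed base atoms, then
    rotate the sugar/backbone about the glycosidic bond to the chi
    target."""
    template = chem.standard_template()
    key = chem.BASE_TO_RESNAME[base] + ("3" if terminal else "")
    rt = template.residues[key]
    names = list(rt.atoms)
    common = [n for n in target_base_atoms if n in names]
    mobile = np.array([rt.atom_pos(n) for n in common])
    target = np.array([target_base_atoms[n] for n in common])
    r, tvec = chem.kabsch_transform(mobile, target)
    pts = np.array([rt.atom_pos(n) for n in names]) @ r.T + tvec
    ptmap = {n: pts[i] for i, n in enumerate(names)}

    if chi_target is not None:
        n_glyc = ptmap[GLYCOSIDIC_N[base]]
        axis = ptmap["C1'"] - n_glyc
        axis = axis / np.linalg.norm(axis)
        base_set = set(BASE_ATOMS[base])
        movable = [i for i, n in enumerate(names) if n not in base_set and n != "C1'"]

        def rotated(delta):
            c, s = np.cos(delta), np.sin(delta)
            kx = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                 [-axis[1], axis[0], 0]]
            )
            rot = np.eye(3) * c + s * kx + (1 - c) * np.outer(axis, axis)
            out = pts.copy()
            for i in movable:
                out[i] = n_glyc + rot @ (out[i] - n_glyc)
            return out

        chi_now = _chi_of(ptmap, base)
        delta = np.radians(chi_target - chi_now)
        # rotate the sugar/backbone about the glycosidic bond; the sign of
        # the rotation depends on the axis orientation, so verify and flip
        for trial in (delta, -delta):
            cand = rotated(trial)
            cmap = {n: cand[i] for i, n in enumerate(names)}
            err = (_chi_of(cmap, base) - chi_target + 180.0) % 360.0 - 180.0
            if abs(err) < 1.0:
                pts = cand
                break
    return names, pts


def build_idealized_coords(
    t: QDHTopology, p: IdealGeometryParams | None = None
) -> Conformer:
    """All-atom idealized reference consistent with the declared fold.

    Tetrad layers are stacked planar units with the stated rise/twist,
    the stem is a coaxial B-form-like duplex, loops and tails are placed
    by geometric interpolation, and a final restrained minimisation
    (covalent terms + the fold's own hydrogen-bond, chi and planarity
    restraints) regularises the assembly.  Deterministic for a given
    topology and parameter set.
    """
    p = p or IdealGeometryParams()
    problems = validate_topology(t)
    if problems:
        raise ValueError("invalid topology: " + "; ".join(problems))

    layers = _stack_order(t)
    slots = _assign_positions(layers, t)
    placed_bases: dict[int, dict[str, np.ndarray]] = {}

    gcgc_pairs = {frozenset((q.g_index, q.c_index)) for q in t.gcgc_member_pairs()}
    stem_pairs = [
        q for q in t.pairs if frozenset((q.g_index, q.c_index)) not in gcgc_pairs
    ]

    # --- tetrad / GCGC layers ---------------------------------------
    z = 0.0
    twist_acc = 0.0
    prev_centroids: dict[int, np.ndarray] = {}
    for li, layer in enumerate(layers):
        if layer.kind == "G-tetrad":
            # choose the cyclic direction that matches the slot assignment
            m0, m1 = layer.members[0], layer.members[1]
            step = (slots[m1] - slots[m0]) % 4
            direction = 1 if step == 1 else -1
            unit = _g_tetrad_layout(direction)
            for m in layer.members:
                ang = slots[m] * 90.0 + twist_acc
                pts = {
                    n: _rz(ang) @ v + np.array([0.0, 0.0, z])
                    for n, v in unit.items()
                }
                placed_bases[m] = pts
        else:  # GCGC tetrad: two WC pairs back-to-back, slipped
            gmap, cmap = _wc_pair_layout()
            g1, c1, g2, c2 = layer.members
            slip = np.array([0.0, 2.0, 0.0])  # offset alignment of the two pairs

            def pair_pts(gm, cm, rot_deg, sign):
                out = {}
                for n, v in gm.items():
                    out[("G", n)] = _rz(rot_deg) @ (v + sign * slip)
                for n, v in cm.items():
                    out[("C", n)] = _rz(rot_deg) @ (v + sign * slip)
                return out

            # orient the layer to best stack under the previous layer
            def score(rot_deg, swap):
                a = pair_pts(gmap, cmap, rot_deg, 1)
                b = pair_pts(gmap, cmap, rot_deg + 180.0, -1)
                first, second = ((g1, c1), (g2, c2)) if not swap else ((g2, c2), (g1, c1))
                centers = {
                    first[0]: np.mean([v for (kk, n), v in a.items() if kk == "G"], axis=0),
                    first[1]: np.mean([v for (kk, n), v in a.items() if kk == "C"], axis=0),
                    second[0]: np.mean([v for (kk, n), v in b.items() if kk == "G"], axis=0),
                    second[1]: np.mean([v for (kk, n), v in b.items() if kk == "C"], axis=0),
                }
                s = 0.0
                for m, ctr in centers.items():
                    for n, pc in prev_centroids.items():
                        if abs(m - n) == 1:
                            s += np.sum((ctr[:2] - pc[:2]) ** 2)
                return s

            best = None
            for swap in (False, True):
                for rot in np.arange(0.0, 360.0, 5.0):
                    sc = score(rot, swap)
                    if best is None or sc < best[0]:
                        best = (sc, rot, swap)
            _, rot, swap = best
            a = pair_pts(gmap, cmap, rot, 1)
            b = pair_pts(gmap, cmap, rot + 180.0, -1)
            first, second = ((g1, c1), (g2, c2)) if not swap else ((g2, c2), (g1, c1))
            for (gi, ci), half in zip((first, second), (a, b)):
                placed_bases[gi] = {
                    n: v + np.array([0.0, 0.0, z])
                    for (kk, n), v in half.items() if kk == "G"
                }
                placed_bases[ci] = {
                    n: v + np.array([0.0, 0.0, z])
                    for (kk, n), v in half.items() if kk == "C"
                }
        prev_centroids = {
            m: np.mean(list(placed_bases[m].values()), axis=0)
            for m in layer.members
        }
        z -= p.rise
        twist_acc += p.twist

    # --- stem pairs ---------------------------------------------------
    gmap, cmap = _wc_pair_layout()
    for q in stem_pairs:
        def pair_at(rot_deg, flip):
            out = {}
            for n, v in gmap.items():
                vv = v * np.array([1, -1, -1]) if flip else v
                out[("G", n)] = _rz(rot_deg) @ vv + np.array([0.0, 0.0, z])
            for n, v in cmap.items():
                vv = v * np.array([1, -1, -1]) if flip else v
                out[("C", n)] = _rz(rot_deg) @ vv + np.array([0.0, 0.0, z])
            return out

        def score(rot_deg, flip):
            pts = pair_at(rot_deg, flip)
            gc = np.mean([v for (kk, n), v in pts.items() if kk == "G"], axis=0)
            cc = np.mean([v for (kk, n), v in pts.items() if kk == "C"], axis=0)
            s = 0.0
            for m, ctr in ((q.g_index, gc), (q.c_index, cc)):
                for n, pc in prev_centroids.items():
                    if abs(m - n) == 1:
                        s += np.sum((ctr[:2] - pc[:2]) ** 2)
            return s

        best = None
        for flip in (False, True):
            for rot in np.arange(0.0, 360.0, 5.0):
                sc = score(rot, flip)
                if best is None or sc < best[0]:
                    best = (sc, rot, flip)
        _, rot, flip = best
        pts = pair_at(rot, flip)
        placed_bases[q.g_index] = {
            n: v for (kk, n), v in pts.items() if kk == "G"
        }
        placed_bases[q.c_index] = {
            n: v for (kk, n), v in pts.items() if kk == "C"
        }
        prev_centroids = {
            q.g_index: np.mean(list(placed_bases[q.g_index].values()), axis=0),
            q.c_index: np.mean(list(placed_bases[q.c_index].values()), axis=0),
        }
        z -= p.rise

    # --- loops and tails by interpolation ----------------------------
    n_res = len(t.sequence)
    anchored = sorted(placed_bases)
    if not anchored:
        raise ValueError("topology anchors no residues (no tetrads or pairs)")
    anchor_ctr = {
        m: np.mean(list(placed_bases[m].values()), axis=0) for m in anchored
    }

    def interpolate_run(start: int, end: int) -> None:
        before = start - 1 if start - 1 in anchor_ctr else None
        after = end + 1 if end + 1 in anchor_ctr else None
        length = end - start + 1
        if before is None and after is None:
            raise ValueError(
                f"residues {start}-{end} cannot be chained to any placed residue"
            )
        if before is not None and after is not None:
            a, b = anchor_ctr[before], anchor_ctr[after]
            mid = 0.5 * (a + b)
            radial = mid[:2]
            nrm = np.linalg.norm(radial)
            outward = (
                np.array([radial[0], radial[1], 0.0]) / nrm
                if nrm > 1e-6 else np.array([1.0, 0.0, 0.0])
            )
            bulge_pt = mid + outward * p.loop_bulge
            for k, m in enumerate(range(start, end + 1)):
                f = (k + 1) / (length + 1)
                pos = (1 - f) * a + f * b + outward * p.loop_bulge * np.sin(np.pi * f)
                _place_interp(m, pos)
        else:
            anchor = before if before is not None else after
            sign = 1.0 if anchor == before else -1.0
            a = anchor_ctr[anchor]
            zdir = np.array([0.0, 0.0, 1.0 if a[2] >= -p.rise else -1.0])
            # tails extend away from the stack, slightly offset radially
            radial = a[:2]
            nrm = np.linalg.norm(radial)
            outward = (
                np.array([radial[0], radial[1], 0.0]) / nrm
                if nrm > 1e-6 else np.array([1.0, 0.0, 0.0])
            )
            run = range(start, end + 1) if anchor == before else range(end, start - 1, -1)
            for k, m in enumerate(run):
                pos = a + zdir * p.rise * (k + 1) + outward * 2.0 * (k + 1)
                _place_interp(m, pos)

    def _place_interp(m: int, pos: np.ndarray) -> None:
        base = t.sequence[m - 1]
        flat = _flat_base(base)
        placed_bases[m] = {n: v + pos for n, v in flat.items()}

    run_start = None
    for m in range(1, n_res + 2):
        if m <= n_res and m not in placed_bases:
            if run_start is None:
                run_start = m
        elif run_start is not None:
            interpolate_run(run_start, m - 1)
            run_start = None

    # --- full residues with chi set per topology ----------------------
    res_index, res_name, atom_name, element, coords = [], [], [], [], []
    template = chem.standard_template()
    for m in range(1, n_res + 1):
        base = t.sequence[m - 1]
        state = t.residue(m).glycosidic
        chi = 60.0 if state == "syn" else 240.0
        names, pts = _place_residue(
            base, placed_bases[m], chi, terminal=(m == n_res)
        )
        key = chem.BASE_TO_RESNAME[base] + ("3" if m == n_res else "")
        rt = template.residues[key]
        for n, e, xyz in zip(rt.atoms, rt.elements, pts):
            res_index.append(m)
            res_name.append(chem.BASE_TO_RESNAME[base])
            atom_name.append(n)
            element.append(e)
            coords.append(xyz)
    conf = Conformer(
        np.array(res_index, int),
        np.array(res_name, dtype=object),
        np.array(atom_name, dtype=object),
        np.array(element, dtype=object),
        np.array(coords, float),
    )

    # --- regularisation under the fold's own restraints ---------------
    # Stage A: the solved base layouts already satisfy every hydrogen
    # bond, so freeze tetrad/pair base atoms and let the sugar-phosphate
    # backbone and loops relax around them.
    hbonds = hbond_restraints(t)
    dihedrals = dihedral_restraints(t)
    planes = planarity_restraints(t)
    ff = engine.ForceField(
        conf,
        distance_restraints=hbonds,
        dihedral_restraints=dihedrals,
        planarity_restraints=planes,
        k_distance=32.0,  # hold the hydrogen-bond network firmly
        k_planarity=25.0,
        # stiff covalent terms: the reference wants geometric fidelity,
        # unlike the deliberately soft constants of the search engine
        k_bond=100.0,
        k_angle=40.0,
        k_improper=20.0,
    )
    anchored_res = {m for tet in t.tetrads for m in tet.members}
    anchored_res |= {i for q in t.pairs for i in (q.g_index, q.c_index)}
    frozen = np.array(
        [
            int(r) in anchored_res and str(a) in BASE_ATOMS[t.sequence[int(r) - 1]]
            for r, a in zip(conf.res_index, conf.atom_name)
        ],
        bool,
    )
    conf = _masked_minimize(conf, ff, ~frozen, max_iter=p.regularize_iter)
    # Stage B: release everything and polish off the residual strain
    conf, _ = engine.minimize(conf, ff, gtol=0.02, max_iter=p.regularize_iter)
    # Stage C: finish at a high hydrogen-bond constant so every window is
    # satisfied strictly, not merely within a tolerance -- the reference
    # must be a cleanly feasible target for the restraints it generates
    ff.set_distance_k_uniform(128.0)
    conf, _ = engine.minimize(conf, ff, gtol=0.02, max_iter=p.regularize_iter)
    return conf


def _masked_minimize(conf, ff, free_mask: np.ndarray, max_iter: int):
    """L-BFGS on the free atoms only (frozen atoms held in place)."""
    from scipy.optimize import minimize as _scipy_minimize

    x_full = conf.coord.copy()
    free = np.where(free_mask)[0]
    state = {"count": 0, "pairs": None}

    def fun(xf):
        x = x_full.copy()
        x[free] = xf.reshape(-1, 3)
        if state["count"] % 25 == 0:
            state["pairs"] = ff.neighbor_pairs(x, skin=1.5)
        state["count"] += 1
        e, g = ff.energy_grad(x, pairs=state["pairs"])
        return e, g[free].ravel()

    res = _scipy_minimize(
        fun, x_full[free].ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": 0.05, "ftol": 1e-12},
    )
    x_full[free] = res.x.reshape(-1, 3)
    return conf.with_coord(x_full)


# ---------------------------------------------------------------------------
# NOE peak simulation

def simulate_noe_peaks(
    conf: Conformer,
    max_distance: float = 6.0,
    noise: NoiseModel | None = None,
) -> list[dict]:
    """Classed NOE peak list from a reference structure.

    Every proton pair within ``max_distance`` is considered (thymine
    methyls are represented by their carbon C7); true distances are
    jittered, quantised into strong/medium/weak by the class boundaries
    (separate boundaries for exchangeable pairs, consistent with the
    restraint windows), and a false-negative fraction is dropped.
    Geminal proton pairs and pairs below the per-type minimum distance
    (fixed-distance or hydrogen-bond territory) are excluded.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)

    # Selector atoms: protons, with group selectors where stereospecific
    # assignment is not assumed -- thymine methyls always collapse onto
    # C7, and (by default) the prochiral methylene protons H2'/H2'' and
    # H5'/H5'' collapse onto their carbon with the same pseudo-atom
    # loosening, mirroring common practice for unassigned methylenes.
    methylene = {"H2'": "C2'", "H2''": "C2'", "H5'": "C5'", "H5''": "C5'"}
    seen_pseudo: set[tuple[int, str]] = set()
    sel_idx, sel_is_methyl = [], []
    for i, (res, nm, el) in enumerate(
        zip(conf.res_index, conf.atom_name, conf.element)
    ):
        nm = str(nm)
        if el == "H" and nm not in ("H71", "H72", "H73"):
            if not noise.stereospecific_methylene and nm in methylene:
                key = (int(res), methylene[nm])
                if key in seen_pseudo:
                    continue
                seen_pseudo.add(key)
                sel_idx.append(conf.atom_index(*key))
                sel_is_methyl.append(True)  # pseudo-carbon selector
            else:
                sel_idx.append(i)
                sel_is_methyl.append(False)
        elif nm == "C7":
            sel_idx.append(i)
            sel_is_methyl.append(True)
    sel_idx = np.array(sel_idx, int)
    coords = conf.coord[sel_idx]

    # geminal exclusion: protons bonded to the same heavy atom
    heavy_parent: dict[int, int] = {}
    bonds, _, _ = chem.chain_terms(conf)
    for i, j, _ in bonds:
        if conf.element[i] == "H" and conf.element[j] != "H":
            heavy_parent[i] = j
        elif conf.element[j] == "H" and conf.element[i] != "H":
            heavy_parent[j] = i

    tree = cKDTree(coords)
    pairs = tree.query_pairs(max_distance, output_type="ndarray")
    rows: list[dict] = []
    for a, b in pairs:
        ia, ib = int(sel_idx[a]), int(sel_idx[b])
        if heavy_parent.get(ia) is not None and heavy_parent.get(ia) == heavy_parent.get(ib):
            continue
        name_a, name_b = str(conf.atom_name[ia]), str(conf.atom_name[ib])
        methyl = bool(sel_is_methyl[a] or sel_is_methyl[b])
        exch = name_a in EXCHANGEABLE_PROTONS or name_b in EXCHANGEABLE_PROTONS
        d_true = float(np.linalg.norm(conf.coord[ia] - conf.coord[ib]))
        d_min = noise.exch_min_distance if exch else noise.min_distance
        if d_true < d_min:
            continue
        d_obs = d_true + rng.normal() * noise.distance_jitter_sd
        b1, b2 = (
            noise.exch_class_boundaries if exch else noise.class_boundaries
        )
        cls = "strong" if d_obs < b1 else ("medium" if d_obs < b2 else "weak")
        if rng.random() < noise.false_negative_rate:
            continue
        rows.append(
            {
                "residue_a": int(conf.res_index[ia]),
                "atom_a": name_a,
                "residue_b": int(conf.res_index[ib]),
                "atom_b": name_b,
                "class": cls,
                "exchangeable": exch,
                "methyl": methyl,
            }
        )
    rows.sort(key=lambda r: (r["residue_a"], r["atom_a"], r["residue_b"], r["atom_b"]))
    return rows


# ---------------------------------------------------------------------------
# CD spectra and melting curves

def _gauss(x, center, width, amp):
    return amp * np.exp(-0.5 * ((x - center) / width) ** 2)


def form1_like_spectrum(grid: np.ndarray | None = None) -> CDSpectrum:
    """Hybrid-type (3+1) signature: positive ~265 nm, shoulder ~290 nm,
    negative ~245 nm."""
    if grid is None:
        grid = np.arange(220.0, 321.0, 1.0)
    y = (
        _gauss(grid, 265.0, 10.0, 10.0)
        + _gauss(grid, 290.0, 9.0, 4.0)
        - _gauss(grid, 245.0, 8.0, 6.0)
    )
    return CDSpectrum(grid, y)


def form2_like_spectrum(grid: np.ndarray | None = None) -> CDSpectrum:
    """Antiparallel signature: positive ~290 nm, negative ~255 nm."""
    if grid is None:
        grid = np.arange(220.0, 321.0, 1.0)
    y = _gauss(grid, 290.0, 10.0, 10.0) - _gauss(grid, 255.0, 9.0, 7.0)
    return CDSpectrum(grid, y)


def simulate_cd_mixture(
    w1: float,
    comp1: CDSpectrum,
    comp2: CDSpectrum,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CDSpectrum:
    """Noisy linear mixture ``w1*comp1 + (1-w1)*comp2``."""
    if not 0.0 <= w1 <= 1.0:
        raise ValueError("w1 must be in [0, 1]")
    if len(comp1.wavelength) != len(comp2.wavelength) or np.any(
        comp1.wavelength != comp2.wavelength
    ):
        raise ValueError("component spectra must share a wavelength grid")
    rng = np.random.default_rng(seed)
    y = w1 * comp1.ellipticity + (1.0 - w1) * comp2.ellipticity
    if noise_sd > 0:
        y = y + rng.normal(size=y.shape) * noise_sd * np.max(np.abs(y))
    return CDSpectrum(comp1.wavelength, y)


def two_state_theta(temp_c: np.ndarray, tm_c: float, dh: float) -> np.ndarray:
    """Two-state van't Hoff folded fraction (dH in kcal/mol, dS = dH/Tm)."""
    t_k = np.asarray(temp_c, float) + 273.15
    tm_k = tm_c + 273.15
    lnk = -(dh / GAS_CONSTANT) * (1.0 / t_k - 1.0 / tm_k)
    return 1.0 / (1.0 + np.exp(lnk))


def simulate_melting_curve(
    tm: float,
    vant_hoff_dh: float = 80.0,
    folded_baseline: Baseline = Baseline(-0.005, 1.0),
    unfolded_baseline: Baseline = Baseline(-0.002, 0.1),
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MeltCurve:
    """Two-state melting curve with sloping linear baselines.

    ``y(T) = theta*y_f(T) + (1-theta)*y_u(T) + noise`` with theta from the
    van't Hoff relation (theta(Tm) = 1/2 exactly).
    """
    if grid is None:
        grid = np.arange(15.0, 96.0, 1.0)
    grid = np.asarray(grid, float)
    if not grid[0] <= tm <= grid[-1]:
        raise ValueError("tm must lie within the temperature grid")
    rng = np.random.default_rng(seed)
    theta = two_state_theta(grid, tm, vant_hoff_dh)
    y = theta * folded_baseline(grid) + (1.0 - theta) * unfolded_baseline(grid)
    if noise_sd > 0:
        y = y + rng.normal(size=y.shape) * noise_sd
    return MeltCurve(grid, y)
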