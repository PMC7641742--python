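"""Distance-geometry embedding and restrained simulated annealing.

The calculation follows the classic solution-NMR protocol for nucleic
acids: an extended chain defines the atom inventory, inter-atomic distance
bounds are assembled from covalent geometry plus the experimental
restraints, metric-matrix distance geometry produces starting coordinates,
and restrained molecular dynamics with simulated annealing refines them.

Energy model (kcal/mol, Angstrom, amu):

* covalent bonds/angles/impropers as harmonic terms around the template
  ideals, plus a purely repulsive soft-sphere nonbonded term (no
  electrostatics) -- the standard treatment for NMR annealing;
* flat-bottom quadratic distance restraints (zero inside [lower, upper]);
* square-well quadratic chi dihedral restraints on the minimal angular
  difference beyond the halfwidth;
* planarity restraints as the squared distances of member ring atoms from
  the unit's best-fit plane.

The annealing schedule reproduces the refinement protocol: heat 300->1000 K
in 14 ps at distance force constant 2 kcal/mol/A^2, equilibrate 6 ps, ramp
the distance constants to 16 (non-exchangeable) / 8 (exchangeable) over
20 ps, equilibrate 50 ps at 1000 K, cool to 300 K in 42 ps, equilibrate
18 ps, save coordinates every 0.5 ps over the final 10 ps, average, and
minimise until the energy gradient falls below 0.1 kcal/mol.  Dihedral
(50 kcal/mol/rad^2) and planarity (1 kcal/mol/A^2) constants are held
throughout.  ``scale_factor`` shortens every stage uniformly for
desk-scale runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import cKDTree

from . import chem
from .chem import Conformer, Ensemble, MolecularTemplate, standard_template
from .restraints import DihedralRestraint, DistanceRestraint, PlanarityRestraint

logger = logging.getLogger(__name__)

__all__ = [
    "AnnealSchedule",
    "BoundsMatrix",
    "EmbedError",
    "EngineError",
    "ForceField",
    "build_chain",
    "build_bounds",
    "embed",
    "fix_chirality",
    "restraint_energy",
    "sa_anneal",
    "minimize",
    "run_pipeline",
]

build_chain = chem.build_chain  # re-export: chains are built by the template layer

KB = 0.0019872041  # kcal/mol/K
TIME_UNIT_FS = 48.88882  # 1 internal time unit in femtoseconds
DEFAULT_UPPER_BOUND = 999.0


class EngineError(RuntimeError):
    pass


class EmbedError(EngineError):
    pass


# ---------------------------------------------------------------------------
# Annealing schedule

@dataclass
class AnnealSchedule:
    """Stage durations (ps) and force constants of the refinement protocol."""

    heat_start_K: float = 300.0
    heat_end_K: float = 1000.0
    heat_ps: float = 14.0
    equil1_ps: float = 6.0
    ramp_ps: float = 20.0
    equil2_ps: float = 50.0
    cool_ps: float = 42.0
    equil3_ps: float = 18.0
    save_window_ps: float = 10.0
    save_interval_ps: float = 0.5
    k_init: float = 2.0  # kcal/mol/A^2, all distance restraints while heating
    k_nonexch: float = 16.0
    k_exch: float = 8.0
    k_dihedral: float = 50.0  # kcal/mol/rad^2
    k_planarity: float = 1.0  # kcal/mol/A^2
    min_gradient: float = 0.1  # kcal/mol termination criterion
    timestep_fs: float = 1.0  # 2 fs is stable but integrates X-H terms poorly at 1000 K
    scale_factor: float = 1.0
    rescale_interval: int = 10  # velocity-rescaling thermostat period (steps)
    repulsive_soft: float = 0.05  # nonbonded scale at high T (full on cooling)
    thermostat: str = "langevin"  # langevin (BAOAB) or rescale
    langevin_gamma: float = 10.0  # friction, 1/ps

    def __post_init__(self):
        for name in ("heat_ps", "equil1_ps", "ramp_ps", "equil2_ps",
                     "cool_ps", "equil3_ps", "save_window_ps",
                     "save_interval_ps", "timestep_fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.scale_factor <= 1:
            raise ValueError("scale_factor must be in (0, 1]")

    def stages(self) -> list[dict]:
        """Ordered stage ledger: name, duration (ps, unscaled), start/end
        temperature, and the distance-constant ramp fractions."""
        t0, t1 = self.heat_start_K, self.heat_end_K
        return [
            {"name": "heat", "ps": self.heat_ps, "T": (t0, t1), "k_ramp": (0.0, 0.0)},
            {"name": "equil1", "ps": self.equil1_ps, "T": (t1, t1), "k_ramp": (0.0, 0.0)},
            {"name": "ramp", "ps": self.ramp_ps, "T": (t1, t1), "k_ramp": (0.0, 1.0)},
            {"name": "equil2", "ps": self.equil2_ps, "T": (t1, t1), "k_ramp": (1.0, 1.0)},
            {"name": "cool", "ps": self.cool_ps, "T": (t1, t0), "k_ramp": (1.0, 1.0)},
            {"name": "equil3", "ps": self.equil3_ps, "T": (t0, t0), "k_ramp": (1.0, 1.0)},
        ]


# ---------------------------------------------------------------------------
# Force field compilation

def _exclusion_pairs(n_atoms: int, bond_pairs: np.ndarray, max_sep: int = 3) -> set:
    """Atom pairs within ``max_sep`` bonds (1-2, 1-3, 1-4 by default)."""
    adj: list[list[int]] = [[] for _ in range(n_atoms)]
    for i, j in bond_pairs:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    excl = set()
    for start in range(n_atoms):
        frontier = {start}
        seen = {start}
        for _ in range(max_sep):
            nxt = set()
            for v in frontier:
                for w in adj[v]:
                    if w not in seen:
                        nxt.add(w)
                        seen.add(w)
            frontier = nxt
        for v in seen:
            if v > start:
                excl.add((start, v))
    return excl


class ForceField:
    """Compiled energy terms for one conformer topology.

    Holds index arrays for covalent terms (from the molecular template),
    restraint terms, and the soft-sphere nonbonded exclusions.  All energy
    methods return (energy, gradient) with analytic gradients.
    """

    def __init__(
        self,
        conf: Conformer,
        template: MolecularTemplate | None = None,
        distance_restraints: list[DistanceRestraint] | None = None,
        dihedral_restraints: list[DihedralRestraint] | None = None,
        planarity_restraints: list[PlanarityRestraint] | None = None,
        k_bond: float = 60.0,
        k_angle: float = 15.0,
        k_improper: float = 10.0,
        k_distance: float = 2.0,
        k_dihedral: float = 50.0,
        k_planarity: float = 1.0,
        k_repulsive: float = 10.0,
        repulsive_scale: float = 0.85,
        nonbonded: bool = True,
    ):
        self.template = template or standard_template()
        self.k_bond, self.k_angle, self.k_improper = k_bond, k_angle, k_improper
        self.k_dihedral, self.k_planarity = k_dihedral, k_planarity
        self.k_repulsive, self.repulsive_scale = k_repulsive, repulsive_scale
        self.nonbonded = nonbonded
        self.n_atoms = conf.n_atoms
        self.masses = np.array([chem.ATOMIC_MASS[e] for e in conf.element])
        radii = np.array([chem.VDW_RADIUS[e] for e in conf.element])

        bonds, angles, impropers = chem.chain_terms(conf, self.template)
        self.bond_idx = np.array([(i, j) for i, j, _ in bonds], int)
        self.bond_ideal = np.array([d for *_, d in bonds])
        self.angle_idx = np.array([(i, j, k) for i, j, k, _ in angles], int)
        self.angle_ideal = np.radians([a for *_, a in angles])
        self.improper_idx = np.array(
            [(a, c, b, d) for c, a, b, d, _ in impropers], int
        )  # torsion a-c-b-d with c the central atom
        self.improper_ideal = np.radians([v for *_, v in impropers])

        self._excluded = _exclusion_pairs(self.n_atoms, self.bond_idx)
        self._radius_sum = radii  # per-atom; pair sum computed lazily
        self._cutoff = 2.0 * radii.max() * repulsive_scale

        # distance restraints
        dr = distance_restraints or []
        self.dist_idx = np.array(
            [(conf.atom_index(*r.atom_a), conf.atom_index(*r.atom_b)) for r in dr],
            int,
        ).reshape(-1, 2)
        self.dist_lower = np.array([r.lower for r in dr])
        self.dist_upper = np.array([r.upper for r in dr])
        self.dist_exch = np.array([r.exchangeable for r in dr], bool)
        self.dist_k = np.full(len(dr), k_distance)

        # chi dihedral restraints
        tr = dihedral_restraints or []
        self.tors_idx = np.array(
            [tuple(conf.atom_index(r.residue, a) for a in r.atoms) for r in tr], int
        ).reshape(-1, 4)
        self.tors_center = np.radians([r.center for r in tr])
        self.tors_halfwidth = np.radians([r.halfwidth for r in tr])

        # planarity units
        self.plane_groups = []
        for p in planarity_restraints or []:
            idx = []
            for res, ring in p.members:
                idx.extend(conf.atom_index(res, a) for a in ring)
            self.plane_groups.append(np.array(idx, int))

    # -- distance-constant ramping ------------------------------------
    def set_distance_k(self, k_nonexch: float, k_exch: float) -> None:
        self.dist_k = np.where(self.dist_exch, k_exch, k_nonexch)

    def set_distance_k_uniform(self, k: float) -> None:
        self.dist_k = np.full(len(self.dist_k), float(k))

    # -- nonbonded neighbor list ---------------------------------------
    def neighbor_pairs(self, coord: np.ndarray, skin: float = 0.5) -> np.ndarray:
        if not self.nonbonded or self.n_atoms < 2:
            return np.empty((0, 2), int)
        tree = cKDTree(coord)
        pairs = tree.query_pairs(self._cutoff + skin, output_type="ndarray")
        if len(pairs) == 0:
            return pairs.reshape(0, 2)
        keep = [
            k for k, (i, j) in enumerate(pairs)
            if (int(i), int(j)) not in self._excluded
        ]
        return pairs[keep].reshape(-1, 2)

    # -- energy terms ---------------------------------------------------
    @staticmethod
    def _scatter(grad, idx, contrib):
        # bincount-based scatter-add: substantially faster than np.add.at
        n = grad.shape[0]
        for k in range(3):
            grad[:, k] += np.bincount(idx, weights=contrib[:, k], minlength=n)

    def _bond_energy(self, x, grad):
        if len(self.bond_idx) == 0:
            return 0.0
        i, j = self.bond_idx[:, 0], self.bond_idx[:, 1]
        dvec = x[i] - x[j]
        d = np.linalg.norm(dvec, axis=1)
        dev = d - self.bond_ideal
        g = (2.0 * self.k_bond * dev / d)[:, None] * dvec
        self._scatter(grad, i, g)
        self._scatter(grad, j, -g)
        return self.k_bond * float(np.sum(dev**2))

    def _angle_energy(self, x, grad):
        if len(self.angle_idx) == 0:
            return 0.0
        a, b, c = (self.angle_idx[:, k] for k in range(3))
        u, v = x[a] - x[b], x[c] - x[b]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cosang = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cosang)
        dev = theta - self.angle_ideal
        # d(theta)/da = -(1/|u|) * (v_hat - cos*u_hat)/sin
        sin = np.sqrt(np.maximum(1.0 - cosang**2, 1e-12))
        uh, vh = u / nu[:, None], v / nv[:, None]
        dth_da = -(vh - cosang[:, None] * uh) / (nu * sin)[:, None]
        dth_dc = -(uh - cosang[:, None] * vh) / (nv * sin)[:, None]
        coef = (2.0 * self.k_angle * dev)[:, None]
        self._scatter(grad, a, coef * dth_da)
        self._scatter(grad, c, coef * dth_dc)
        self._scatter(grad, b, -coef * (dth_da + dth_dc))
        return self.k_angle * float(np.sum(dev**2))

    @staticmethod
    def _torsion_and_grad(x, quads):
        """Vectorized signed torsion phi and d(phi)/d(positions) for
        index quartets ``quads`` (m, 4)."""
        p0, p1, p2, p3 = (x[quads[:, k]] for k in range(4))
        b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        m1 = np.cross(n1, b2 / nb2[:, None])
        phi = np.arctan2(np.sum(m1 * n2, axis=1), np.sum(n1 * n2, axis=1))
        sn1 = np.maximum(np.sum(n1 * n1, axis=1), 1e-12)
        sn2 = np.maximum(np.sum(n2 * n2, axis=1), 1e-12)
        g0 = (nb2 / sn1)[:, None] * n1
        g3 = (-nb2 / sn2)[:, None] * n2
        c12 = (np.sum(b1 * b2, axis=1) / nb2**2)[:, None]
        c32 = (np.sum(b3 * b2, axis=1) / nb2**2)[:, None]
        g1 = -(1.0 + c12) * g0 + c32 * g3
        g2 = c12 * g0 - (1.0 + c32) * g3
        return phi, (g0, g1, g2, g3)

    def _improper_energy(self, x, grad):
        if len(self.improper_idx) == 0:
            return 0.0
        phi, gs = self._torsion_and_grad(x, self.improper_idx)
        dev = np.arctan2(np.sin(phi - self.improper_ideal),
                         np.cos(phi - self.improper_ideal))
        coef = (2.0 * self.k_improper * dev)[:, None]
        for k, g in enumerate(gs):
            self._scatter(grad, self.improper_idx[:, k], coef * g)
        return self.k_improper * float(np.sum(dev**2))

    def _distance_restraint_energy(self, x, grad):
        if len(self.dist_idx) == 0:
            return 0.0
        i, j = self.dist_idx[:, 0], self.dist_idx[:, 1]
        dvec = x[i] - x[j]
        d = np.linalg.norm(dvec, axis=1)
        viol = np.where(
            d > self.dist_upper, d - self.dist_upper,
            np.where(d < self.dist_lower, d - self.dist_lower, 0.0),
        )
        coef = (2.0 * self.dist_k * viol / np.maximum(d, 1e-9))[:, None]
        g = coef * dvec
        self._scatter(grad, i, g)
        self._scatter(grad, j, -g)
        return float(np.sum(self.dist_k * viol**2))

    def _dihedral_restraint_energy(self, x, grad):
        if len(self.tors_idx) == 0:
            return 0.0
        phi, gs = self._torsion_and_grad(x, self.tors_idx)
        delta = np.arctan2(np.sin(phi - self.tors_center),
                           np.cos(phi - self.tors_center))
        viol = np.sign(delta) * np.maximum(np.abs(delta) - self.tors_halfwidth, 0.0)
        coef = (2.0 * self.k_dihedral * viol)[:, None]
        for k, g in enumerate(gs):
            self._scatter(grad, self.tors_idx[:, k], coef * g)
        return self.k_dihedral * float(np.sum(viol**2))

    def _planarity_energy(self, x, grad):
        e = 0.0
        for idx in self.plane_groups:
            pts = x[idx]
            centered = pts - pts.mean(axis=0)
            # normal of the best-fit plane = smallest covariance eigenvector
            _, vecs = np.linalg.eigh(centered.T @ centered)
            normal = vecs[:, 0]
            dist = centered @ normal
            e += self.k_planarity * float(np.sum(dist**2))
            # best-fit plane is optimal, so only the explicit dependence remains
            self._scatter(grad, idx, (2.0 * self.k_planarity * dist)[:, None] * normal)
        return e

    def _repulsive_energy(self, x, grad, pairs):
        if pairs is None or len(pairs) == 0:
            return 0.0
        i, j = pairs[:, 0], pairs[:, 1]
        dvec = x[i] - x[j]
        d = np.linalg.norm(dvec, axis=1)
        s = self.repulsive_scale * (self._radius_sum[i] + self._radius_sum[j])
        viol = np.minimum(d - s, 0.0)
        coef = (2.0 * self.k_repulsive * viol / np.maximum(d, 1e-9))[:, None]
        g = coef * dvec
        self._scatter(grad, i, g)
        self._scatter(grad, j, -g)
        return self.k_repulsive * float(np.sum(viol**2))

    def energy_grad(
        self,
        coord: np.ndarray,
        pairs: np.ndarray | None = None,
        terms: tuple[str, ...] = ("covalent", "restraints", "repulsive"),
        components: bool = False,
    ):
        x = coord.reshape(-1, 3)
        grad = np.zeros_like(x)
        comp = {}
        if "covalent" in terms:
            comp["bond"] = self._bond_energy(x, grad)
            comp["angle"] = self._angle_energy(x, grad)
            comp["improper"] = self._improper_energy(x, grad)
        if "restraints" in terms:
            comp["distance"] = self._distance_restraint_energy(x, grad)
            comp["dihedral"] = self._dihedral_restraint_energy(x, grad)
            comp["planarity"] = self._planarity_energy(x, grad)
        if "repulsive" in terms and self.nonbonded:
            if pairs is None:
                pairs = self.neighbor_pairs(x)
            comp["repulsive"] = self._repulsive_energy(x, grad, pairs)
        total = float(sum(comp.values()))
        if components:
            return total, grad, comp
        return total, grad


def restraint_energy(
    conf: Conformer,
    distance_r: list[DistanceRestraint],
    dihedral_r: list[DihedralRestraint],
    planarity_r: list[PlanarityRestraint],
    k_distance: float = 2.0,
    k_dihedral: float = 50.0,
    k_planarity: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Restraint-only energy and per-atom gradient for a conformer.

    Zero for a conformer satisfying every restraint window (flat-bottom
    potentials); always non-negative.
    """
    ff = ForceField(
        conf,
        distance_restraints=distance_r,
        dihedral_restraints=dihedral_r,
        planarity_restraints=planarity_r,
        k_distance=k_distance,
        k_dihedral=k_dihedral,
        k_planarity=k_planarity,
        nonbonded=False,
    )
    e, g = ff.energy_grad(conf.coord, terms=("restraints",))
    return e, g


# ---------------------------------------------------------------------------
# Distance bounds and metric-matrix embedding

@dataclass
class BoundsMatrix:
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        if self.lower.shape != self.upper.shape or self.lower.ndim != 2:
            raise ValueError("bounds must be square matrices of equal shape")
        if np.any(self.lower > self.upper + 1e-9):
            raise ValueError("lower bound exceeds upper bound")


def build_bounds(
    conf: Conformer,
    restraints: list[DistanceRestraint],
    template: MolecularTemplate | None = None,
    default_upper: float = DEFAULT_UPPER_BOUND,
    smooth: bool = True,
) -> BoundsMatrix:
    """Assemble and triangle-smooth the inter-atomic distance bounds.

    Covalent 1-2 and 1-3 distances are fixed at their ideal values;
    restraint pairs are intersected with [target-minus, target+plus]; all
    other pairs default to lower = sum of van der Waals radii, upper =
    ``default_upper``.  Upper bounds are smoothed with the triangle
    inequality (Floyd-style all-pairs shortest path).
    """
    n = conf.n_atoms
    radii = np.array([chem.VDW_RADIUS[e] for e in conf.element])
    lower = radii[:, None] + radii[None, :]
    upper = np.full((n, n), default_upper)

    ff_template = template or standard_template()
    bonds, angles, _ = chem.chain_terms(conf, ff_template)
    bond_len = {}
    for i, j, d in bonds:
        lower[i, j] = lower[j, i] = upper[i, j] = upper[j, i] = d
        bond_len[(i, j)] = bond_len[(j, i)] = d
    for i, j, k, ang in angles:
        d13 = np.sqrt(
            bond_len[(i, j)] ** 2 + bond_len[(j, k)] ** 2
            - 2 * bond_len[(i, j)] * bond_len[(j, k)] * np.cos(np.radians(ang))
        )
        lower[i, k] = lower[k, i] = upper[i, k] = upper[k, i] = d13

    for r in restraints:
        i = conf.atom_index(*r.atom_a)
        j = conf.atom_index(*r.atom_b)
        lo = max(lower[i, j], r.lower) if upper[i, j] >= default_upper else lower[i, j]
        hi = min(upper[i, j], r.upper)
        if lo > hi:
            lo = hi  # conflicting windows collapse to the tighter bound
        lower[i, j] = lower[j, i] = lo
        upper[i, j] = upper[j, i] = hi

    np.fill_diagonal(lower, 0.0)
    np.fill_diagonal(upper, 0.0)
    if smooth:
        upper = shortest_path(upper, method="FW", directed=False)
        lower = np.minimum(lower, upper)
    return BoundsMatrix(lower, upper)


def embed(bounds: BoundsMatrix, seed: int) -> np.ndarray:
    """Metric-matrix distance-geometry embedding of a random distance
    sample drawn between the bounds (seeded); best-3-eigenvalue
    projection.  Chirality is unresolved and fixed downstream."""
    rng = np.random.default_rng(seed)
    lo, hi = bounds.lower, bounds.upper
    n = lo.shape[0]
    # correlated sampling: one global fraction plus small per-pair jitter
    # keeps the sampled matrix close to a consistent metric, which plain
    # independent uniform draws do not
    f0 = rng.uniform(0.3, 0.7)
    frac = np.clip(f0 + 0.1 * rng.standard_normal((n, n)), 0.0, 1.0)
    frac = np.triu(frac, 1)
    frac = frac + frac.T
    d = lo + frac * (hi - lo)
    np.fill_diagonal(d, 0.0)

    d2 = d**2
    row = d2.mean(axis=1)
    gram = -0.5 * (d2 - row[:, None] - row[None, :] + d2.mean())
    vals, vecs = np.linalg.eigh(gram)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    if vals[0] <= 1e-8:
        raise EmbedError(
            "bounds are not embeddable: metric matrix has no positive eigenvalue"
        )
    top = np.maximum(vals[:3], 0.0)
    coords = vecs[:, :3] * np.sqrt(top)[None, :]
    return coords


def fix_chirality(conf: Conformer, ff: ForceField) -> Conformer:
    """Resolve the embedding's handedness ambiguity.

    Signed improper torsions at the chiral sugar carbons are compared with
    the template ideals; if the majority is inverted the model is
    mirrored (z -> -z)."""
    x = conf.coord
    chiral = [
        k for k, quad in enumerate(ff.improper_idx)
        if abs(abs(np.degrees(ff.improper_ideal[k])) - 90.0) < 60.0
    ]  # impropers well away from planarity carry handedness
    if not chiral:
        return conf
    quads = ff.improper_idx[chiral]
    ideal = ff.improper_ideal[chiral]
    phi, _ = ForceField._torsion_and_grad(x, quads)
    agree = np.sum(np.sign(phi) == np.sign(ideal))
    if agree < len(chiral) / 2:
        x = x * np.array([1.0, 1.0, -1.0])
        return conf.with_coord(x)
    return conf


# ---------------------------------------------------------------------------
# Minimisation and dynamics

def minimize(
    conf: Conformer,
    ff: ForceField,
    gtol: float = 0.1,
    max_iter: int = 1000,
) -> tuple[Conformer, dict]:
    """Gradient-based minimisation until the energy gradient criterion
    ``gtol`` (kcal/mol) is met or the iteration cap is reached.

    Returns the minimised conformer (with total energy) and an info dict;
    hitting the cap sets ``info['converged'] = False`` (a warning, not an
    error)."""
    x0 = conf.coord.ravel()
    state = {"count": 0, "pairs": None}

    def fun(x):
        # refresh the nonbonded neighbor list periodically; the generous
        # skin keeps it valid between rebuilds at minimisation step sizes
        if state["count"] % 25 == 0:
            state["pairs"] = ff.neighbor_pairs(x.reshape(-1, 3), skin=1.5)
        state["count"] += 1
        e, g = ff.energy_grad(x.reshape(-1, 3), pairs=state["pairs"])
        return e, g.ravel()

    res = _scipy_minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
    )
    e_final, _ = ff.energy_grad(res.x.reshape(-1, 3))
    e_initial, _ = ff.energy_grad(conf.coord)
    if e_final > e_initial:  # descent contract: never accept an uphill result
        return conf.with_coord(conf.coord, e_initial), {
            "converged": False, "n_iter": int(res.nit), "message": "no descent",
        }
    info = {
        "converged": bool(res.success or np.max(np.abs(res.jac)) < gtol),
        "n_iter": int(res.nit),
        "message": str(res.message),
    }
    if not info["converged"]:
        logger.warning("minimisation stopped before gradient criterion: %s",
                       info["message"])
    return conf.with_coord(res.x.reshape(-1, 3), e_final), info


def _init_velocities(rng, masses: np.ndarray, temperature: float) -> np.ndarray:
    if temperature <= 0:
        return np.zeros((len(masses), 3))
    sigma = np.sqrt(KB * temperature / masses)
    return rng.normal(size=(len(masses), 3)) * sigma[:, None]


def _current_temperature(vel: np.ndarray, masses: np.ndarray) -> float:
    ke = 0.5 * float(np.sum(masses[:, None] * vel**2))
    dof = 3 * len(masses)
    return 2.0 * ke / (dof * KB)


def sa_anneal(
    conf: Conformer,
    ff: ForceField,
    schedule: AnnealSchedule,
    seed: int,
) -> Conformer:
    """Velocity-Verlet dynamics with a velocity-rescaling thermostat
    through the full stage sequence; returns the average of the
    coordinates saved over the final window (unminimised)."""
    dt = schedule.timestep_fs / TIME_UNIT_FS
    rng = np.random.default_rng(seed)
    masses = ff.masses
    x = conf.coord.copy()
    vel = _init_velocities(rng, masses, schedule.heat_start_K)

    # reset mutable force-field state so a run is a pure function of
    # (conformer, schedule, seed)
    ff.set_distance_k_uniform(schedule.k_init)
    k_rep_base = ff.k_repulsive
    ff.k_repulsive = k_rep_base * schedule.repulsive_soft
    pairs = ff.neighbor_pairs(x)
    _, grad = ff.energy_grad(x, pairs=pairs)
    force = -grad

    saved: list[np.ndarray] = []
    stages = schedule.stages()
    total_steps_by_stage = [
        max(1, int(round(s["ps"] * schedule.scale_factor * 1000.0
                         / schedule.timestep_fs)))
        for s in stages
    ]
    save_every = max(
        1, int(round(schedule.save_interval_ps * schedule.scale_factor * 1000.0
                     / schedule.timestep_fs))
    )
    save_steps = max(
        1, int(round(schedule.save_window_ps * schedule.scale_factor * 1000.0
                     / schedule.timestep_fs))
    )

    for stage, n_steps in zip(stages, total_steps_by_stage):
        t_start, t_end = stage["T"]
        k0, k1 = stage["k_ramp"]
        is_last = stage["name"] == "equil3"
        for step in range(n_steps):
            f = (step + 1) / n_steps
            target_t = t_start + (t_end - t_start) * f
            kf = k0 + (k1 - k0) * f
            ff.dist_k = np.where(
                ff.dist_exch,
                schedule.k_init + kf * (schedule.k_exch - schedule.k_init),
                schedule.k_init + kf * (schedule.k_nonexch - schedule.k_init),
            )
            # soft nonbonded while hot (lets the chain rearrange), ramped
            # to full strength as the system cools
            if stage["name"] == "cool":
                rep_f = schedule.repulsive_soft + (1.0 - schedule.repulsive_soft) * f
            elif stage["name"] == "equil3":
                rep_f = 1.0
            else:
                rep_f = schedule.repulsive_soft
            ff.k_repulsive = k_rep_base * rep_f
            if schedule.thermostat == "langevin":
                # BAOAB splitting: one force evaluation per step
                vel += 0.5 * dt * force / masses[:, None]
                x += 0.5 * dt * vel
                gamma_dt = schedule.langevin_gamma * schedule.timestep_fs * 1e-3
                c1 = np.exp(-gamma_dt)
                sigma = np.sqrt(KB * max(target_t, 0.0) / masses)
                vel = c1 * vel + np.sqrt(1.0 - c1**2) * sigma[:, None] \
                    * rng.standard_normal(vel.shape)
                x += 0.5 * dt * vel
                if step % schedule.rescale_interval == 0:
                    pairs = ff.neighbor_pairs(x)
                _, grad = ff.energy_grad(x, pairs=pairs)
                force = -grad
                vel += 0.5 * dt * force / masses[:, None]
            else:
                # velocity Verlet with periodic velocity rescaling
                vel += 0.5 * dt * force / masses[:, None]
                x += dt * vel
                if step % schedule.rescale_interval == 0:
                    pairs = ff.neighbor_pairs(x)
                _, grad = ff.energy_grad(x, pairs=pairs)
                force = -grad
                vel += 0.5 * dt * force / masses[:, None]
                if step % schedule.rescale_interval == 0 and target_t >= 0:
                    t_now = _current_temperature(vel, masses)
                    if t_now > 1e-12:
                        vel *= np.sqrt(target_t / t_now)
            if not np.all(np.isfinite(x)):
                raise EngineError(
                    f"non-finite coordinates during stage {stage['name']!r}"
                )
            if is_last and step >= n_steps - save_steps and (
                (n_steps - 1 - step) % save_every == 0
            ):
                saved.append(x.copy())

    ff.k_repulsive = k_rep_base
    avg = np.mean(saved, axis=0) if saved else x
    return conf.with_coord(avg)


def run_pipeline(
    topology,
    noe: list[DistanceRestraint],
    hbond: list[DistanceRestraint],
    dihedral: list[DihedralRestraint],
    planarity: list[PlanarityRestraint],
    n_structures: int = 100,
    n_select: int = 10,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
    template: MolecularTemplate | None = None,
    regularize_iter: int = 2000,
    final_min_iter: int = 3000,
) -> Ensemble:
    """Full calculation: ``n_structures`` independent embed -> anneal ->
    minimise runs, energies ranked, ``n_select`` lowest flagged.

    Each run derives its randomness from (seed, run index); failed runs
    are excluded and logged, and an error is raised only if all fail."""
    if n_select > n_structures:
        raise ValueError("n_select cannot exceed n_structures")
    schedule = schedule or AnnealSchedule()
    conf0 = chem.build_chain(topology.sequence, template)
    distance_all = list(noe) + list(hbond)
    ff = ForceField(
        conf0,
        template=template,
        distance_restraints=distance_all,
        dihedral_restraints=dihedral,
        planarity_restraints=planarity,
        k_distance=schedule.k_init,
        k_dihedral=schedule.k_dihedral,
        k_planarity=schedule.k_planarity,
    )
    bounds = build_bounds(conf0, distance_all, template)

    conformers: list[Conformer] = []
    failures = 0
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s) % (2**31) for s in ss.generate_state(2 * n_structures)]
    for run in range(n_structures):
        try:
            coords = embed(bounds, run_seeds[2 * run])
            conf = fix_chirality(conf0.with_coord(coords), ff)
            # regularise against the full-strength restraint set with soft
            # repulsion: pulls the embedding into the restraint windows
            # before dynamics, which the annealing alone cannot always do
            # at desk scale
            ff.set_distance_k(schedule.k_nonexch, schedule.k_exch)
            k_rep_base = ff.k_repulsive
            ff.k_repulsive = k_rep_base * schedule.repulsive_soft
            conf, _ = minimize(conf, ff, gtol=schedule.min_gradient,
                               max_iter=regularize_iter)
            ff.k_repulsive = k_rep_base
            conf = sa_anneal(conf, ff, schedule, run_seeds[2 * run + 1])
            ff.set_distance_k(schedule.k_nonexch, schedule.k_exch)
            conf, _ = minimize(conf, ff, gtol=schedule.min_gradient,
                               max_iter=final_min_iter)
            conformers.append(conf)
        except EngineError as err:
            failures += 1
            logger.warning("run %d failed: %s", run, err)
    if not conformers:
        raise EngineError(f"all {n_structures} runs failed")
    if failures:
        logger.info("%d/%d runs excluded", failures, n_structures)
    return Ensemble(conformers).select_lowest(n_select)
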