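"""Distance bounds, embedding, energy terms, dynamics and minimisation."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from qdhfold import chem, engine
from qdhfold import restraints as R


@pytest.fixture(scope="module")
def dimer():
    return chem.build_chain("GT")


@pytest.fixture(scope="module")
def dimer_ff(dimer):
    dr = [
        R.DistanceRestraint((1, "H8"), (2, "H6"), 3.8, 0.9, 0.9, "medium"),
        R.DistanceRestraint((1, "H1'"), (2, "H3"), 4.0, 1.0, 1.0, "strong", True),
    ]
    tr = [
        R.DihedralRestraint(1, R.CHI_ATOMS["G"], 240.0, 70.0),
        R.DihedralRestraint(2, R.CHI_ATOMS["T"], 60.0, 40.0),
    ]
    pr = [R.PlanarityRestraint("pair", ((1, R.PURINE_RING), (2, R.PYRIMIDINE_RING)))]
    return engine.ForceField(
        dimer, distance_restraints=dr, dihedral_restraints=tr,
        planarity_restraints=pr,
    )


class TestBuildBounds:
    def test_bonded_pair_bounds_are_tight(self, dimer):
        b = engine.build_bounds(dimer, [], smooth=False)
        bonds, _, _ = chem.chain_terms(dimer)
        i, j, ideal = bonds[0]
        assert b.lower[i, j] == pytest.approx(ideal)
        assert b.upper[i, j] == pytest.approx(ideal)

    def test_restraint_window_applied(self, dimer):
        r = R.DistanceRestraint((1, "H8"), (2, "H6"), 3.8, 0.9, 0.9, "medium")
        b = engine.build_bounds(dimer, [r], smooth=False)
        i = dimer.atom_index(1, "H8")
        j = dimer.atom_index(2, "H6")
        assert b.lower[i, j] == pytest.approx(2.9)
        assert b.upper[i, j] == pytest.approx(4.7)

    def test_triangle_smoothing_toy_chain(self):
        # 3 atoms bonded in a line with u=1.5 each and a long restraint
        # u(1,3)=5: smoothing caps it at 1.5+1.5=3.0
        lower = np.zeros((3, 3))
        upper = np.full((3, 3), 999.0)
        for i, j in ((0, 1), (1, 2)):
            lower[i, j] = lower[j, i] = upper[i, j] = upper[j, i] = 1.5
        upper[0, 2] = upper[2, 0] = 5.0
        np.fill_diagonal(upper, 0.0)
        from scipy.sparse.csgraph import shortest_path

        smoothed = shortest_path(upper, method="FW", directed=False)
        assert smoothed[0, 2] == pytest.approx(3.0)

    def test_missing_restraint_atom_rejected(self, dimer):
        r = R.DistanceRestraint((1, "H99"), (2, "H6"), 3.8, 0.9, 0.9, "medium")
        with pytest.raises(KeyError):
            engine.build_bounds(dimer, [r])


@pytest.fixture(scope="module")
def tetrahedron():
    pts = np.array(
        [[0, 0, 0], [1, 0, 0],
         [0.5, np.sqrt(3) / 2, 0],
         [0.5, np.sqrt(3) / 6, np.sqrt(2 / 3)]]
    )
    d = squareform(pdist(pts))
    return pts, engine.BoundsMatrix(d.copy(), d.copy())


class TestEmbed:
    @staticmethod
    def _rmsd_up_to_reflection(xyz, pts):
        best = np.inf
        for mirror in (1.0, -1.0):
            cand = xyz * np.array([1.0, 1.0, mirror])
            r, t = chem.kabsch_transform(cand, pts)
            best = min(best, float(np.sqrt(np.mean(
                np.sum((cand @ r.T + t - pts) ** 2, axis=1)))))
        return best

    def test_exact_bounds_recover_tetrahedron(self, tetrahedron):
        pts, bounds = tetrahedron
        xyz = engine.embed(bounds, seed=5)
        assert self._rmsd_up_to_reflection(xyz, pts) < 1e-6

    def test_same_seed_identical(self, tetrahedron):
        _, bounds = tetrahedron
        assert np.array_equal(engine.embed(bounds, 7), engine.embed(bounds, 7))

    def test_different_seeds_equal_up_to_rigid_motion(self, tetrahedron):
        pts, bounds = tetrahedron
        for seed in (1, 2, 3):
            assert self._rmsd_up_to_reflection(engine.embed(bounds, seed), pts) < 1e-6

    def test_degenerate_bounds_rejected(self):
        z = np.zeros((4, 4))
        with pytest.raises(engine.EmbedError, match="embeddable"):
            engine.embed(engine.BoundsMatrix(z, z), 0)


class TestRestraintEnergy:
    def test_zero_inside_flat_bottom(self, dimer):
        d = float(np.linalg.norm(dimer.position(1, "H8") - dimer.position(2, "H6")))
        r = R.DistanceRestraint((1, "H8"), (2, "H6"), d, 1.0, 1.0, "medium")
        e, g = engine.restraint_energy(dimer, [r], [], [])
        assert e == 0.0
        assert np.allclose(g, 0.0)

    def test_quadratic_beyond_upper_bound(self, dimer):
        d = float(np.linalg.norm(dimer.position(1, "H8") - dimer.position(2, "H6")))
        # distance exceeds the upper bound by exactly 0.5 A at k=2
        r = R.DistanceRestraint((1, "H8"), (2, "H6"), d - 1.0, 0.5, 0.5, "strong")
        e, _ = engine.restraint_energy(dimer, [r], [], [], k_distance=2.0)
        assert e == pytest.approx(2.0 * 0.25, abs=1e-9)

    def test_energy_non_negative_on_random_coords(self, dimer, dimer_ff):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = dimer.coord + rng.normal(scale=0.5, size=dimer.coord.shape)
            e, _ = dimer_ff.energy_grad(x, terms=("restraints",))
            assert e >= 0.0


class TestGradients:
    @pytest.mark.parametrize(
        "terms", [("covalent",), ("restraints",), ("repulsive",)]
    )
    def test_analytic_matches_finite_difference(self, dimer, dimer_ff, terms):
        rng = np.random.default_rng(17)
        x = dimer.coord + rng.normal(scale=0.3, size=dimer.coord.shape)
        pairs = dimer_ff.neighbor_pairs(x)
        _, g = dimer_ff.energy_grad(x, pairs=pairs, terms=terms)
        h = 1e-6
        idx = rng.choice(dimer.n_atoms, size=12, replace=False)
        for i in idx:
            for k in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, k] += h
                xm[i, k] -= h
                ep, _ = dimer_ff.energy_grad(xp, pairs=pairs, terms=terms)
                em, _ = dimer_ff.energy_grad(xm, pairs=pairs, terms=terms)
                assert g[i, k] == pytest.approx((ep - em) / (2 * h), abs=1e-5)


class TestMinimize:
    def test_already_minimal_unchanged(self, dimer):
        # the ideal chain is the exact minimum of the covalent terms
        ff = engine.ForceField(dimer, nonbonded=False)
        out, info = engine.minimize(dimer, ff, max_iter=50)
        assert np.allclose(out.coord, dimer.coord, atol=1e-3)

    def test_stretched_bond_restored(self, dimer):
        ff = engine.ForceField(dimer, nonbonded=False)
        bonds, _, _ = chem.chain_terms(dimer)
        # stretch the terminal hydroxyl proton bond (a leaf atom)
        i = dimer.atom_index(2, "O3'")
        j = dimer.atom_index(2, "HO3'")
        ideal = next(d for a, b, d in bonds if {a, b} == {i, j})
        x = dimer.coord.copy()
        u = (x[j] - x[i]) / np.linalg.norm(x[j] - x[i])
        x[j] = x[i] + (ideal + 0.5) * u
        out, _ = engine.minimize(dimer.with_coord(x), ff, gtol=1e-4, max_iter=500)
        assert np.linalg.norm(out.coord[j] - out.coord[i]) == pytest.approx(
            ideal, abs=1e-3
        )

    def test_energy_never_increases(self, dimer, dimer_ff):
        rng = np.random.default_rng(3)
        x = dimer.coord + rng.normal(scale=0.2, size=dimer.coord.shape)
        start = dimer.with_coord(x)
        e0, _ = dimer_ff.energy_grad(x)
        out, _ = engine.minimize(start, dimer_ff, max_iter=40)
        assert out.energy <= e0 + 1e-9


class TestAnnealSchedule:
    def test_stage_ledger_matches_protocol(self):
        s = engine.AnnealSchedule()
        stages = s.stages()
        assert [st["ps"] for st in stages] == [14.0, 6.0, 20.0, 50.0, 42.0, 18.0]
        assert stages[0]["T"] == (300.0, 1000.0)
        assert stages[4]["T"] == (1000.0, 300.0)
        assert (s.save_window_ps, s.save_interval_ps) == (10.0, 0.5)
        assert (s.k_init, s.k_nonexch, s.k_exch) == (2.0, 16.0, 8.0)
        assert (s.k_dihedral, s.k_planarity) == (50.0, 1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            engine.AnnealSchedule(heat_ps=-1.0)
        with pytest.raises(ValueError):
            engine.AnnealSchedule(scale_factor=0.0)


class TestDynamics:
    def test_zero_restraints_at_zero_kelvin_static(self, dimer):
        ff = engine.ForceField(dimer, nonbonded=False)
        sched = engine.AnnealSchedule(
            heat_start_K=0.0, heat_end_K=0.0, scale_factor=0.01
        )
        out = engine.sa_anneal(dimer, ff, sched, seed=0)
        # ideal chain, zero forces, zero initial velocities: nothing moves
        assert np.allclose(out.coord, dimer.coord, atol=1e-8)

    def test_seeded_dynamics_reproducible(self, dimer, dimer_ff):
        sched = engine.AnnealSchedule(scale_factor=0.002)
        a = engine.sa_anneal(dimer, dimer_ff, sched, seed=5)
        b = engine.sa_anneal(dimer, dimer_ff, sched, seed=5)
        assert np.array_equal(a.coord, b.coord)

    def test_restraint_energy_decreases_from_violated_start(self, dimer, dimer_ff):
        rng = np.random.default_rng(8)
        x = dimer.coord + rng.normal(scale=0.4, size=dimer.coord.shape)
        e0, _ = dimer_ff.energy_grad(x)
        sched = engine.AnnealSchedule(scale_factor=0.01)
        out = engine.sa_anneal(dimer.with_coord(x), dimer_ff, sched, seed=2)
        out, _ = engine.minimize(out, dimer_ff, max_iter=300)
        assert out.energy < e0
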