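"""Membrane particle layer: boundary sets, initialization laws, walks."""

import numpy as np
import pytest
from scipy import stats

from shapemem import particles as pt
from shapemem.cpm import CPMParams, Lattice, metropolis_attempt


def _ball_lattice(r=8, margin=6):
    n = 2 * (r + margin)
    c = n / 2.0
    x, y, z = np.meshgrid(*[np.arange(n) + 0.5 - c] * 3, indexing="ij")
    ids = (x * x + y * y + z * z <= r * r).astype(np.int32)
    return Lattice(ids)


class TestBoundarySites:
    def test_single_site_cell(self):
        ids = np.zeros((5, 5, 5), np.int32)
        ids[2, 2, 2] = 1
        np.testing.assert_array_equal(
            pt.boundary_sites(Lattice(ids), 1), [[2, 2, 2]]
        )

    def test_3x3x3_block_has_26_boundary_sites(self):
        ids = np.zeros((7, 7, 7), np.int32)
        ids[2:5, 2:5, 2:5] = 1
        assert len(pt.boundary_sites(Lattice(ids), 1)) == 26

    def test_matches_exhaustive_neighbor_scan(self):
        lat = _ball_lattice(r=8)
        got = {tuple(s) for s in pt.boundary_sites(lat, 1)}
        expected = set()
        for site in map(tuple, np.argwhere(lat.cell_ids == 1)):
            if any(lat.id_at(u) != 1 for u in lat.neighbors6(site)) or \
                    len(list(lat.neighbors6(site))) < 6:
                expected.add(site)
        assert got == expected

    def test_empty_cell_rejected(self):
        lat = _ball_lattice(r=4)
        with pytest.raises(ValueError, match="empty"):
            pt.boundary_sites(lat, 3)


class TestShapeWeightedInit:
    def test_zero_particles(self, rng):
        lat = _ball_lattice(r=5)
        ps = pt.init_particles_shape_weighted(lat, 1, 0, rng)
        assert len(ps) == 0

    def test_sphere_is_uniform(self, rng):
        """Equal boundary distances make the d^3 rule uniform (chi^2)."""
        lat = _ball_lattice(r=8)
        bs = pt.boundary_sites(lat, 1)
        ps = pt.init_particles_shape_weighted(lat, 1, 10_000, rng)
        index = {tuple(s): k for k, s in enumerate(bs)}
        counts = np.zeros(len(bs))
        for p in ps.positions:
            counts[index[tuple(p)]] += 1
        # bin sites by octant to keep expected counts comfortably high
        com = lat.centroid(1)
        octant = ((bs + 0.5 - com) > 0) @ [4, 2, 1]
        obs = np.array([counts[octant == k].sum() for k in range(8)])
        exp = np.array([np.sum(octant == k) for k in range(8)], float)
        exp = exp / exp.sum() * obs.sum()
        _, p_val = stats.chisquare(obs, exp)
        assert p_val > 0.01

    def test_frequency_follows_distance_cubed(self, rng):
        """Per-site frequency correlates with d^3 weights (Spearman > 0.9)."""
        from shapemem.synthetic_shapes import tune_to_target

        fx = tune_to_target(0.092)
        lat = Lattice.from_mask(fx.mask.mask, margin=8)
        bs = pt.boundary_sites(lat, 1)
        com = lat.centroid(1)
        d = np.linalg.norm(bs + 0.5 - com, axis=1)
        ps = pt.init_particles_shape_weighted(lat, 1, 100_000, rng)
        index = {tuple(s): k for k, s in enumerate(bs)}
        counts = np.zeros(len(bs))
        for p in ps.positions:
            counts[index[tuple(p)]] += 1
        # aggregate into 20 distance shells to beat per-site Poisson noise
        shells = np.quantile(d, np.linspace(0, 1, 21))
        which = np.clip(np.searchsorted(shells, d, side="right") - 1, 0, 19)
        freq = np.array([counts[which == k].mean() for k in range(20)])
        weight = np.array([(d[which == k] ** 3).mean() for k in range(20)])
        rho, _ = stats.spearmanr(freq, weight)
        assert rho > 0.9

    def test_two_shell_acceptance_ratio(self, rng):
        """Boundary shells at distances r1 < r2 are loaded ~ (r2/r1)^3."""
        n = 44
        c = n / 2.0
        x, y, z = np.meshgrid(*[np.arange(n) + 0.5 - c] * 3, indexing="ij")
        rr = x * x + y * y + z * z
        bar = (y * y + z * z <= 9) & (np.abs(x) <= 14)
        ids = ((rr <= 25) | bar).astype(np.int32)
        # a ball of radius 5 with a radius-3 bar reaching x = +-14
        lat = Lattice(ids)
        bs = pt.boundary_sites(lat, 1)
        com = lat.centroid(1)
        d = np.linalg.norm(bs + 0.5 - com, axis=1)
        near = d < 6.0
        far = d > 11.0
        ps = pt.init_particles_shape_weighted(lat, 1, 100_000, rng)
        pd_ = np.linalg.norm(ps.positions + 0.5 - com, axis=1)
        rate_near = np.sum(pd_ < 6.0) / near.sum()
        rate_far = np.sum(pd_ > 11.0) / far.sum()
        expected = (d[far].mean() / d[near].mean()) ** 3
        assert rate_far / rate_near == pytest.approx(expected, rel=0.25)

class TestUniformInit:
    def test_uniform_over_boundary(self, rng):
        from shapemem.synthetic_shapes import make_teardrop

        fx = make_teardrop(taper=0.12)
        lat = Lattice.from_mask(fx.mask.mask, margin=6)
        bs = pt.boundary_sites(lat, 1)
        ps = pt.init_particles_uniform(lat, 1, 10_000, rng)
        com = lat.centroid(1)
        octant = ((bs + 0.5 - com) > 0) @ [4, 2, 1]
        index = {tuple(s): k for k, s in enumerate(bs)}
        counts = np.zeros(len(bs))
        for p in ps.positions:
            counts[index[tuple(p)]] += 1
        obs = np.array([counts[octant == k].sum() for k in range(8)])
        exp = np.array([np.sum(octant == k) for k in range(8)], float)
        exp = exp / exp.sum() * obs.sum()
        _, p_val = stats.chisquare(obs, exp)
        assert p_val > 0.01

    def test_seeded_determinism(self):
        lat = _ball_lattice(r=6)
        a = pt.init_particles_uniform(lat, 1, 50, np.random.default_rng(3))
        b = pt.init_particles_uniform(lat, 1, 50, np.random.default_rng(3))
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_single_particle_lands_on_boundary(self, rng):
        lat = _ball_lattice(r=5)
        ps = pt.init_particles_uniform(lat, 1, 1, rng)
        assert tuple(ps.positions[0]) in {tuple(s) for s in pt.boundary_sites(lat, 1)}


class TestReattachment:
    def test_particle_on_boundary_untouched(self, rng):
        lat = _ball_lattice(r=6)
        ps = pt.init_particles_uniform(lat, 1, 20, rng)
        before = ps.positions.copy()
        pt.reattach_after_copy(ps, lat, changed_site=(1, 1, 1), rng=rng)
        np.testing.assert_array_equal(ps.positions, before)

    def test_stranded_particle_moves_to_a_nearest_boundary_site(self, rng):
        ids = np.zeros((9, 9, 9), np.int32)
        ids[2:7, 2:7, 2:7] = 1
        lat = Lattice(ids)
        # an interior site of the 5^3 block; nearest boundary sites (there
        # are three, at distance 1) come from a brute-force oracle
        start = np.array([3, 3, 3])
        ps = pt.ParticleSet(start.reshape(1, 3), cell=1)
        bmask = pt.boundary_mask(lat, 1)
        bs = np.argwhere(bmask)
        dmin = np.min(np.linalg.norm(bs - start, axis=1))
        pt.reattach_after_copy(ps, lat, changed_site=(3, 3, 3), rng=rng)
        landed = ps.positions[0]
        assert bmask[tuple(landed)]
        assert np.linalg.norm(landed - start) == pytest.approx(dmin)

    def test_counts_conserved_under_dynamics(self, rng):
        """Particle counts never change through rounding dynamics."""
        lat = _ball_lattice(r=6)
        p = CPMParams(target_volume={1: float(lat.volumes[1])},
                      target_surface={1: float(lat.areas[1])})
        ps = pt.init_particles_uniform(lat, 1, 40, rng)
        for _ in range(3000):
            metropolis_attempt(lat, p, rng, particle_set=ps)
        assert len(ps) == 40
        bmask = pt.boundary_mask(lat, 1)
        assert all(bmask[tuple(q)] for q in ps.positions)


class TestDiffusion:
    def test_zero_step_is_identity(self, rng):
        lat = _ball_lattice(r=6)
        ps = pt.init_particles_uniform(lat, 1, 30, rng, step=0.0)
        before = ps.positions.copy()
        pt.diffuse_particles(ps, lat, rng)
        np.testing.assert_array_equal(ps.positions, before)

    def test_step_one_candidates_on_flat_patch(self, rng):
        """On a flat boundary patch, step 1 reaches exactly the in-plane
        sites at distances 1 and sqrt(2), both inside the open annulus
        (0.5, 1.5); nothing farther, nothing off the surface."""
        ids = np.zeros((8, 12, 12), np.int32)
        ids[1:4, 1:11, 1:11] = 1      # a slab; top face is flat
        lat = Lattice(ids)
        ps = pt.ParticleSet(np.array([[3, 6, 6]]), cell=1, step=1.0)
        seen = set()
        for k in range(400):
            ps.positions[0] = (3, 6, 6)
            pt.diffuse_particles(ps, lat, np.random.default_rng(k))
            seen.add(tuple(int(v) for v in ps.positions[0]))
        expected = {
            (3, 6 + dy, 6 + dz)
            for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            if (dy, dz) != (0, 0)
        }
        assert seen == expected

    def test_mean_squared_displacement_matches_annulus(self, rng):
        """Single-step MSD on a large sphere equals the annulus average.

        The open annulus (1.5, 2.5) on the digital surface contains sites
        at squared distances 4, 5 and 6, so the expected jump MSD is their
        candidate-weighted mean (~s^2 + 1), computed here by a brute-force
        per-particle candidate enumeration.
        """
        lat = _ball_lattice(r=10)
        ps = pt.init_particles_uniform(lat, 1, 2000, rng, step=2.0)
        before = ps.positions.copy()
        bmask = pt.boundary_mask(lat, 1)
        bs = np.argwhere(bmask)
        expected = []
        for p in before[:300]:
            d2 = np.sum((bs - p) ** 2, axis=1)
            sel = d2[(d2 > 1.5 ** 2) & (d2 < 2.5 ** 2)]
            if len(sel):
                expected.append(sel.mean())
        pt.diffuse_particles(ps, lat, rng)
        msd = np.mean(np.sum((ps.positions - before) ** 2, axis=1))
        assert msd == pytest.approx(np.mean(expected), rel=0.05)
        assert 1.5 ** 2 < msd < 2.5 ** 2

    def test_counts_and_boundary_membership_preserved(self, rng):
        lat = _ball_lattice(r=7)
        ps = pt.init_particles_uniform(lat, 1, 100, rng, step=2.0)
        bmask = pt.boundary_mask(lat, 1)
        for _ in range(20):
            pt.diffuse_particles(ps, lat, rng)
        assert len(ps) == 100
        assert all(bmask[tuple(q)] for q in ps.positions)


class TestCellVector:
    def test_single_particle_gives_unit_vector(self):
        cv = pt.cell_vector(np.array([[7, 4, 4]]), np.array([4.5, 4.5, 4.5]))
        np.testing.assert_allclose(cv, [1.0, 0, 0], atol=1e-9)

    def test_antipodal_particles_cancel(self):
        cv = pt.cell_vector(
            np.array([[7, 4, 4], [1, 4, 4]]), np.array([4.5, 4.5, 4.5])
        )
        np.testing.assert_allclose(cv, 0.0, atol=1e-9)

    def test_uniform_sphere_has_small_resultant(self, rng):
        """Law of large numbers: |CV|/N < 0.05 for 10^4 uniform particles."""
        lat = _ball_lattice(r=10)
        ps = pt.init_particles_uniform(lat, 1, 10_000, rng)
        cv = pt.cell_vector(ps.positions, lat.centroid(1))
        assert np.linalg.norm(cv) / 10_000 < 0.05

    def test_no_particles_rejected(self):
        with pytest.raises(ValueError):
            pt.cell_vector(np.empty((0, 3)), np.zeros(3))


class TestPartition:
    def test_counts_sum_exactly(self, rng):
        from shapemem.cpm import divide_cell

        for seed in range(10):
            lat = _ball_lattice(r=6)
            r2 = np.random.default_rng(seed)
            ps = pt.init_particles_uniform(lat, 1, 37, r2)
            cv = r2.standard_normal(3)
            plus_id, minus_id = divide_cell(lat, 1, cv)
            n_plus, n_minus = pt.partition_particles(ps, lat, plus_id, minus_id)
            assert n_plus + n_minus == 37

    def test_all_on_one_side(self):
        from shapemem.cpm import divide_cell

        lat = _ball_lattice(r=6)
        bs = pt.boundary_sites(lat, 1)
        com = lat.centroid(1)
        plus_sites = bs[(bs[:, 0] + 0.5 - com[0]) > 2.0]
        ps = pt.ParticleSet(plus_sites[:10], cell=1)
        plus_id, minus_id = divide_cell(lat, 1, np.array([1.0, 0, 0]))
        n_plus, n_minus = pt.partition_particles(ps, lat, plus_id, minus_id)
        assert (n_plus, n_minus) == (10, 0)
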