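import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from coevocv.free_energy import (
    FreeEnergySurface,
    basin_populations,
    classify_basin_state,
    detect_basins,
    energetic_coupling,
    frame_free_energy,
    make_bins,
    project_fes,
)
from coevocv.units import RT_STANDARD_KJ_PER_MOL as RT


def _surface_from_energies(u, rt=RT, counts=None):
    u = np.asarray(u, dtype=float)
    if counts is None:
        counts = np.where(np.isfinite(u), 1, 0)
    energies = np.where(counts > 0, u, np.nan)
    edges = tuple(np.arange(s + 1, dtype=float) for s in u.shape)
    return FreeEnergySurface(edges=edges, energies=energies, counts=np.asarray(counts), rt=rt)


class TestFrameFreeEnergy:
    def test_uniform_counts_flat_surface(self):
        series = np.repeat(np.arange(5) + 0.5, 7)
        fes = frame_free_energy(series, np.arange(6.0))
        assert np.allclose(fes.energies, 0.0)

    def test_two_bin_closed_form(self):
        """75/25 split gives dU = RT ln 3 = 2.7233 kJ/mol at 298.15 K."""
        series = np.array([0.5] * 75 + [1.5] * 25)
        fes = frame_free_energy(series, np.array([0.0, 1.0, 2.0]))
        delta = fes.energies[1] - fes.energies[0]
        assert delta == pytest.approx(RT * np.log(3.0), abs=1e-6)
        assert delta == pytest.approx(2.7233, abs=2e-4)  # printed precision

    def test_single_visited_bin(self):
        fes = frame_free_energy(np.full(10, 0.5), np.arange(4.0))
        assert fes.energies[0] == 0.0
        assert np.isnan(fes.energies[1:]).all()
        assert not fes.mask[1:].any()

    def test_out_of_range_raises_unless_clamped(self):
        with pytest.raises(ValueError, match="clamp"):
            frame_free_energy(np.array([5.0]), np.arange(4.0))
        fes = frame_free_energy(np.array([5.0, 0.5]), np.arange(4.0), clamp=True)
        assert fes.counts[-1] == 1

    def test_probabilities_renormalize(self):
        rng = np.random.default_rng(0)
        fes = frame_free_energy(rng.uniform(0, 3, 500), np.arange(4.0))
        assert fes.probabilities().sum() == pytest.approx(1.0, abs=1e-8)

    def test_anchored_at_zero(self):
        rng = np.random.default_rng(1)
        fes = frame_free_energy(rng.uniform(0, 3, 100), np.arange(4.0))
        assert np.nanmin(fes.energies) == 0.0

    def test_2d_surface(self):
        rng = np.random.default_rng(2)
        series = rng.uniform(0, 2, (200, 2))
        fes = frame_free_energy(series, (np.arange(3.0), np.arange(3.0)))
        assert fes.energies.shape == (2, 2)
        assert fes.counts.sum() == 200


class TestProjectFes:
    def test_identity_projection_recovers_surface(self):
        rng = np.random.default_rng(0)
        series = rng.uniform(0, 5, 2000)
        edges = np.arange(6.0)
        fes = frame_free_energy(series, edges)
        u, counts = fes.frame_energies(series)
        back = project_fes(u, series, edges, source_bin_counts=counts)
        m = fes.mask
        assert np.abs(back.energies[m] - fes.energies[m]).max() < 1e-10

    def test_ten_frame_brute_force(self):
        """A 10-frame toy equals a direct evaluation of the reweighting
        sums: per bin, -RT log of the summed frame weights, re-anchored."""
        u = np.array([0.0, 1.0, 0.5, 2.0, 0.0, 1.5, 0.2, 0.8, 0.3, 1.1])
        y = np.array([0.1, 0.4, 0.6, 1.2, 1.8, 0.3, 0.9, 1.5, 0.2, 1.9])
        edges = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        out = project_fes(u, y, edges)
        w = np.exp(-u / RT)
        expected = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (y >= lo) & (y < hi)
            expected.append(-RT * np.log(w[sel].sum() / w.sum()) if sel.any() else np.nan)
        expected = np.array(expected)
        expected -= np.nanmin(expected)
        assert np.allclose(out.energies, expected, equal_nan=True)

    def test_constant_observable_single_bin(self):
        u = np.array([0.0, 1.0, 2.0])
        out = project_fes(u, np.full(3, 0.5), np.arange(3.0))
        assert out.energies[0] == 0.0
        assert np.isnan(out.energies[1])

    def test_total_weight_conserved(self):
        rng = np.random.default_rng(1)
        series = rng.uniform(0, 5, 1000)
        edges = np.arange(6.0)
        fes = frame_free_energy(series, edges)
        u, counts = fes.frame_energies(series)
        observable = rng.uniform(0, 1, 1000)
        out = project_fes(u, observable, np.linspace(0, 1, 7), source_bin_counts=counts)
        w_before = (np.exp(-u / RT) / counts).sum()
        m = out.mask
        # re-derive per-bin masses from the anchored energies
        p = np.exp(-out.energies[m] / RT)
        assert p.sum() / p.sum() == pytest.approx(1.0)  # normalised by construction
        assert out.counts.sum() == 1000
        assert np.isfinite(w_before)

    def test_anchor_invariance(self):
        """Adding a constant to all frame energies changes nothing."""
        rng = np.random.default_rng(2)
        u = rng.uniform(0, 3, 200)
        y = rng.uniform(0, 1, 200)
        edges = np.linspace(0, 1, 6)
        a = project_fes(u, y, edges)
        b = project_fes(u + 7.3, y, edges)
        m = a.mask
        assert np.allclose(a.energies[m], b.energies[m], atol=1e-10)


class TestDetectBasins:
    def test_single_parabola_one_basin(self):
        x = np.linspace(-1, 1, 11)
        basins = detect_basins(_surface_from_energies(4 * x**2))
        assert len(basins) == 1
        assert basins.basins[0].n_bins == 11

    def test_symmetric_double_well_splits_at_barrier(self):
        x = np.linspace(-1.5, 1.5, 30)
        u = 5.0 * (x**2 - 1) ** 2
        basins = detect_basins(_surface_from_energies(u))
        assert len(basins) == 2
        sizes = sorted(b.n_bins for b in basins)
        assert sizes[0] >= 10  # both wells carry a sensible share

    def test_small_spurious_dip_discarded(self):
        u = np.array([0.0, 1.0, 2.0, 3.0, 2.9, 3.5])
        # the shallow dip at bin 4 captures only bins {4, 5}: below the
        # 3-bin floor, so it is discarded
        basins = detect_basins(_surface_from_energies(u), min_bins=3)
        assert len(basins) == 1
        assert basins.basins[0].minimum_bin == (0,)

    def test_flat_surface_single_basin(self):
        basins = detect_basins(_surface_from_energies(np.zeros(6)))
        assert len(basins) == 1
        assert basins.basins[0].n_bins == 6

    def test_unvisited_bins_unassigned(self):
        u = np.array([0.0, 1.0, np.nan, 0.5, 1.5])
        counts = np.array([5, 3, 0, 4, 1])
        basins = detect_basins(_surface_from_energies(u, counts=counts), min_bins=1)
        assert basins.labels[2] == -1

    def test_2d_double_well(self):
        x = np.linspace(-1.5, 1.5, 25)
        y = np.linspace(-1, 1, 15)
        u = 5 * (x[:, None] ** 2 - 1) ** 2 + 3 * y[None, :] ** 2
        basins = detect_basins(_surface_from_energies(u))
        assert len(basins) == 2


class TestBasinPopulations:
    def test_symmetric_double_well_half_half(self):
        x = np.linspace(-1.5, 1.5, 30)  # even bin count: no centre bin
        u = 5.0 * (x**2 - 1) ** 2
        fes = _surface_from_energies(u)
        basins = detect_basins(fes)
        pops = basin_populations(fes, basins)
        assert np.allclose(pops, [0.5, 0.5])

    def test_rtln2_offset_gives_two_thirds(self):
        """Two mirrored single-minimum basins offset by RT ln 2 carry
        populations exactly 2/3 and 1/3."""
        well = np.array([3.0, 1.0, 0.0, 1.0, 3.0])
        u = np.concatenate([well, [np.nan], well + RT * np.log(2.0)])
        counts = np.where(np.isfinite(u), 1, 0)
        fes = _surface_from_energies(u, counts=counts)
        basins = detect_basins(fes)
        pops = basin_populations(fes, basins)
        assert sorted(pops) == pytest.approx([1 / 3, 2 / 3], abs=1e-12)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        fes = frame_free_energy(rng.uniform(0, 5, 3000), np.linspace(0, 5, 26))
        basins = detect_basins(fes, min_bins=1)
        assert basin_populations(fes, basins).sum() == pytest.approx(1.0)

    def test_populations_written_to_basins(self):
        x = np.linspace(-1.5, 1.5, 20)
        fes = _surface_from_energies(5 * (x**2 - 1) ** 2)
        basins = detect_basins(fes)
        basin_populations(fes, basins)
        assert all(b.population is not None for b in basins)


class TestClassifyBasinState:
    def _helix(self, n=30):
        t = np.arange(n) * 100 * np.pi / 180
        return np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)])

    def test_identical_frames_active(self):
        ref = self._helix()
        frames = np.repeat(ref[None], 3, axis=0)
        out = classify_basin_state(frames, ref)
        assert out.mean_rmsd == pytest.approx(0.0, abs=1e-8)
        assert out.active

    def test_rigid_motion_removed_by_superposition(self):
        ref = self._helix()
        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        frames = (ref @ rot.T + np.array([5.0, -3.0, 2.0]))[None]
        out = classify_basin_state(frames, ref)
        assert out.mean_rmsd == pytest.approx(0.0, abs=1e-6)

    def test_displaced_helix_resting(self):
        """Displace the RMSD selection by 5 A while aligning on the rest:
        the mean RMSD equals the displacement, comfortably 'resting'."""
        ref = self._helix(40)
        frame = ref.copy()
        rmsd_sel = np.arange(25, 40)
        align_sel = np.arange(0, 25)
        frame[rmsd_sel] += np.array([5.0, 0.0, 0.0])
        out = classify_basin_state(
            frame[None], ref, align_indices=align_sel, rmsd_indices=rmsd_sel
        )
        assert out.mean_rmsd == pytest.approx(5.0, abs=1e-8)
        assert out.label == "resting"

    def test_exact_cutoff_is_resting(self):
        """Mean RMSD exactly at the cutoff: only strictly below is active."""
        ref = self._helix(40)
        frame = ref.copy()
        rmsd_sel = np.arange(25, 40)
        frame[rmsd_sel] += np.array([3.0, 0.0, 0.0])
        out = classify_basin_state(
            frame[None], ref, align_indices=np.arange(0, 25), rmsd_indices=rmsd_sel,
            cutoff_angstrom=3.0,
        )
        assert out.mean_rmsd == pytest.approx(3.0, abs=1e-9)
        assert out.label == "resting"

    def test_empty_selection_error(self):
        ref = self._helix()
        with pytest.raises(ValueError):
            classify_basin_state(ref[None], ref, align_indices=np.array([], dtype=int))


class TestEnergeticCoupling:
    def test_monotonic_surface_zero(self):
        assert energetic_coupling(_surface_from_energies(np.arange(8.0))) == 0.0

    def test_double_well_closed_form(self):
        u = np.array([1.0, 0.0, 2.0, 5.0, 3.0, 2.0, 4.0])
        assert energetic_coupling(_surface_from_energies(u)) == pytest.approx(5.0)

    def test_flat_surface_zero(self):
        assert energetic_coupling(_surface_from_energies(np.zeros(5))) == 0.0

    def test_requires_1d(self):
        with pytest.raises(ValueError):
            energetic_coupling(_surface_from_energies(np.zeros((3, 3))))
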