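"""Covariance handling, LCMV weights, pseudo-T contrast, virtual electrodes."""

import numpy as np
import pandas as pd
import pytest

from opmbeta.beamform import (BeamformerWeights, CovarianceMatrix,
                              PseudoTImage, compute_covariance,
                              extract_virtual_electrode, lcmv_weights,
                              peak_voxel, pseudo_t_map, regularize,
                              source_grid)
from opmbeta.forward import sarvas_leadfield
from opmbeta.geometry import HeadModel
from opmbeta.synthcohort import Recording


def _rec(data, fs, array, n_trials=4):
    tl = data.shape[1] // n_trials
    table = pd.DataFrame({"onset_sample": np.arange(n_trials) * tl,
                          "condition": ["index", "little"] * (n_trials // 2)})
    return Recording(data, fs, table, array)


class TestCovariance:
    def test_textbook_two_channel_example(self):
        # hand-computed sample covariance (ddof=1) of a 2x4 array
        x = np.array([[1.0, 2.0, 3.0, 4.0],
                      [2.0, 1.0, 4.0, 3.0]])
        want = np.cov(x, ddof=1)
        # arithmetic oracle, fully written out:
        mx, my = 2.5, 2.5
        sxx = sum((v - mx) ** 2 for v in x[0]) / 3
        syy = sum((v - my) ** 2 for v in x[1]) / 3
        sxy = sum((a - mx) * (b - my) for a, b in zip(x[0], x[1])) / 3
        assert np.allclose(want, [[sxx, sxy], [sxy, syy]])

    def test_white_noise_off_diagonals_vanish(self, small_array, rng):
        fs = 200.0
        n = 200_000
        data = rng.standard_normal((12, n))
        data = np.vstack([data, rng.standard_normal(
            (small_array.n_channels - 12, n))])
        rec = _rec(data, fs, small_array)
        cov = compute_covariance(rec, band=(10.0, 40.0))
        c = cov.matrix
        off = c[~np.eye(c.shape[0], dtype=bool)]
        diag = np.diag(c).mean()
        assert np.abs(off).max() < 5.0 / np.sqrt(n) * diag / 0.3

    def test_rank_one_for_fixed_topography(self, small_array, rng):
        fs = 200.0
        topo = rng.standard_normal(small_array.n_channels)
        s = np.sin(2 * np.pi * 20.0 * np.arange(8000) / fs)
        rec = _rec(np.outer(topo, s), fs, small_array)
        cov = compute_covariance(rec, band=(15.0, 25.0))
        vals = np.linalg.eigvalsh(cov.matrix)[::-1]
        assert vals[1] < 1e-10 * vals[0]


class TestRegularize:
    def test_identity_scaled(self):
        cov = CovarianceMatrix(np.eye(3), (1, 40), 100, np.arange(3))
        out = regularize(cov, 0.05)
        assert np.allclose(out.matrix, 1.05 * np.eye(3))

    def test_fraction_zero_is_identity_operation(self):
        m = np.diag([4.0, 1.0])
        cov = CovarianceMatrix(m, (1, 40), 100, np.arange(2))
        assert np.array_equal(regularize(cov, 0.0).matrix, m)

    def test_five_percent_of_max_eigenvalue(self):
        cov = CovarianceMatrix(np.diag([4.0, 1.0]), (1, 40), 100,
                               np.arange(2))
        out = regularize(cov, 0.05)
        assert np.allclose(out.matrix, np.diag([4.2, 1.2]))

    def test_negative_fraction_rejected(self):
        cov = CovarianceMatrix(np.eye(2), (1, 40), 100, np.arange(2))
        with pytest.raises(ValueError):
            regularize(cov, -0.1)


@pytest.fixture(scope="module")
def grid_setup(head, small_array):
    grid = source_grid(head, spacing=0.02)
    lead = sarvas_leadfield(head, grid, small_array)
    return grid, lead


class TestLCMVWeights:
    def test_identity_covariance_gives_matched_filter(self, grid_setup,
                                                      small_array):
        grid, lead = grid_setup
        cov = CovarianceMatrix(np.eye(small_array.n_channels), (1, 48),
                               10_000, np.arange(small_array.n_channels))
        w = lcmv_weights(lead, cov)
        for v in (0, len(grid) // 2, len(grid) - 1):
            l_or = lead.fields[v] @ (lead.basis[v] @ w.orientations[v])
            expected = l_or / (l_or @ l_or)
            assert np.allclose(w.weights[v], expected, rtol=1e-8)

    def test_unit_gain_constraint_everywhere(self, grid_setup, small_array,
                                             rng):
        grid, lead = grid_setup
        a = rng.standard_normal((small_array.n_channels,
                                 small_array.n_channels))
        cov = CovarianceMatrix(a @ a.T / small_array.n_channels
                               + 0.1 * np.eye(small_array.n_channels),
                               (1, 48), 10_000,
                               np.arange(small_array.n_channels))
        w = lcmv_weights(lead, cov)
        gains = np.array([
            w.weights[v] @ (lead.fields[v] @ (lead.basis[v]
                                              @ w.orientations[v]))
            for v in range(len(grid))])
        assert np.allclose(gains, 1.0, atol=1e-8)

    def test_planted_source_peaks_at_true_voxel(self, head, small_array,
                                                grid_setup, rng):
        grid, lead = grid_setup
        true_v = np.argmin(np.linalg.norm(
            grid - np.array([0.02, 0.01, 0.04]), axis=1))
        ori = lead.basis[true_v, 0]
        topo = lead.fields[true_v] @ np.array([1.0, 0.0])
        n = 20_000
        s = rng.standard_normal(n)
        noise = 0.05 * np.abs(topo).max() * rng.standard_normal(
            (small_array.n_channels, n))
        data = np.outer(topo, s) + noise
        cov = CovarianceMatrix(np.cov(data, ddof=1), (1, 48), n,
                               np.arange(small_array.n_channels))
        w = lcmv_weights(lead, regularize(cov, 0.05))
        # projected power, noise-normalised to suppress depth bias
        power = np.einsum("vc,cd,vd->v", w.weights, cov.matrix, w.weights)
        norm = np.einsum("vc,vc->v", w.weights, w.weights)
        assert int(np.argmax(power / norm)) == int(true_v)
        del ori


class TestPseudoT:
    def test_arithmetic_of_normalisation(self):
        p_act, p_ctl = 1.0, 3.0
        assert (p_act - p_ctl) / (p_act + p_ctl) == -0.5

    def test_scaling_invariance(self, head, small_array, grid_setup, rng):
        grid, lead = grid_setup
        fs = 200.0
        n_trials, tl = 8, int(3.5 * fs)
        data = 1e-13 * rng.standard_normal((small_array.n_channels,
                                            n_trials * tl))
        rec = _rec(data, fs, small_array, n_trials=n_trials)
        cov = regularize(compute_covariance(rec, (13.0, 30.0)), 0.05)
        w = lcmv_weights(lead, cov)
        img1 = pseudo_t_map(w, rec)
        rec2 = rec.copy()
        rec2.data = rec.data * 7.3
        img2 = pseudo_t_map(w, rec2)
        assert np.allclose(img1.values, img2.values, atol=1e-12)

    def test_unmodulated_source_near_zero(self, head, small_array,
                                          grid_setup, rng):
        grid, lead = grid_setup
        fs = 200.0
        n_trials, tl = 84, int(3.5 * fs)
        v = len(grid) // 3
        topo = lead.fields[v] @ np.array([1.0, 0.0])
        s = rng.standard_normal(n_trials * tl)
        rec = _rec(np.outer(topo, s), fs, small_array, n_trials=n_trials)
        cov = regularize(compute_covariance(rec, (13.0, 30.0)), 0.05)
        w = lcmv_weights(lead, cov)
        img = pseudo_t_map(w, rec)
        assert abs(img.values[v]) < 0.05

    def test_peak_voxel_tie_breaks_to_lowest_index(self):
        vals = np.array([0.2, -0.5, 0.1, -0.5])
        img = PseudoTImage(np.zeros((4, 3)), 0.01, vals)
        assert peak_voxel(img, mode="min") == 1


class TestVirtualElectrode:
    def test_exact_recovery_under_unit_gain(self, head, small_array,
                                            grid_setup, rng):
        grid, lead = grid_setup
        fs = 200.0
        v = 5
        ori2 = np.array([1.0, 0.0])
        topo = lead.fields[v] @ ori2
        s = rng.standard_normal(4 * int(3.5 * fs))
        rec = _rec(np.outer(topo, s), fs, small_array)
        cov = CovarianceMatrix(
            np.outer(topo, topo) + 1e-6 * topo @ topo
            * np.eye(small_array.n_channels) / small_array.n_channels,
            (1, 48), s.size, np.arange(small_array.n_channels))
        w = lcmv_weights(lead, cov)
        ve = extract_virtual_electrode(w, rec, v)
        # recovered up to the sign of the chosen orientation
        sign = np.sign(ve.timecourse @ s)
        assert np.allclose(sign * ve.timecourse, s, rtol=1e-6, atol=1e-8)
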