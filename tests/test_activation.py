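"""Rasterization, scan dictionaries, NNLS deconvolution and image slicing."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import nnls

from swaps.activation import (PrecursorImage, ScanDictionary, assemble_and_slice,
                              build_im_grid, build_scan_dictionary, mz_bin,
                              naive_intensity, partition_dictionary_blocks,
                              rasterize_frame, run_activation, solve_scan_activation,
                              CubeStore)
from swaps.io import Ms1Frame
from swaps.library import IsotopeEnvelope, PrecursorCandidate


def _frame(points, fid=0, t=1.0):
    return Ms1Frame(fid, t, np.array(points, dtype=float))


def _dict_from_envelopes(envelopes):
    """ScanDictionary straight from {candidate_id: (bins, abundances)}."""
    all_bins = np.unique(np.concatenate([b for b, _ in envelopes.values()]))
    rows, cols, vals, ids = [], [], [], []
    for j, (cid, (bins, abs_)) in enumerate(sorted(envelopes.items())):
        rows.extend(np.searchsorted(all_bins, bins))
        cols.extend([j] * len(bins))
        vals.extend(abs_)
        ids.append(cid)
    mat = sp.coo_matrix((vals, (rows, cols)),
                        shape=(len(all_bins), len(ids))).tocsc()
    return ScanDictionary(all_bins, mat, np.array(ids))


def _sparse_frame(bins, im_grid, dense):
    return rasterize_sparse(bins, im_grid, dense)


def rasterize_sparse(bins, im_grid, dense):
    from swaps.activation import SparseFrameMatrix

    return SparseFrameMatrix(np.asarray(bins, dtype=np.int64),
                             sp.csc_matrix(np.asarray(dense, dtype=float)),
                             np.asarray(im_grid, dtype=float))


class TestRasterize:
    def test_floor_bin_rule(self):
        grid = np.array([0.9])
        sfm = rasterize_frame(_frame([[500.005, 0.9, 100.0]]), 0.01, grid)
        assert sfm.bins.tolist() == [50000]

    def test_points_in_one_cell_sum(self):
        grid = np.array([0.9])
        sfm = rasterize_frame(_frame([[500.001, 0.9, 40.0], [500.009, 0.9, 60.0]]),
                              0.01, grid)
        assert sfm.matrix.toarray().sum() == pytest.approx(100.0)

    def test_empty_frame(self):
        sfm = rasterize_frame(_frame(np.empty((0, 3))), 0.01, np.array([0.9]))
        assert sfm.matrix.nnz == 0

    def test_off_grid_point_snaps_to_nearest_within_half_step(self):
        grid = np.array([0.90, 0.92])
        sfm = rasterize_frame(_frame([[500.0, 0.909, 10.0]]), 0.01, grid)
        col = sfm.matrix.toarray()
        # nearest grid point to 0.909 is 0.90 (|0.009| < |0.011| <= half step)
        assert col[0, 0] == pytest.approx(10.0)

    def test_far_off_grid_point_dropped(self):
        grid = np.array([0.90, 1.00])
        sfm = rasterize_frame(_frame([[500.0, 1.08, 10.0]]), 0.01, grid)
        # 0.08 from the nearest grid value, beyond half a grid step
        assert sfm.matrix.sum() == 0.0


class TestScanDictionary:
    def _cand(self, cid, t1, t2):
        env = IsotopeEnvelope(np.array([[500.0, 0.6], [500.5, 0.3]]), 500.0,
                              np.array([50000, 50050]))
        return PrecursorCandidate(id=cid, modified_sequence=f"S{cid}", charge=2,
                                  is_decoy=False, pair_id=cid, envelope=env,
                                  rt_pred=(t1 + t2) / 2, rt_window=(t1, t2),
                                  im_center=1.0, im_window=(0.9, 1.1))

    def test_window_inclusion(self):
        d = build_scan_dictionary([self._cand(0, 10.0, 11.6)], 10.4, 0.01)
        assert d.n_candidates == 1

    def test_boundary_inclusive(self):
        d = build_scan_dictionary([self._cand(0, 10.0, 11.6)], 11.6, 0.01)
        assert d.n_candidates == 1

    def test_admitted_count_matches_brute_force(self):
        rng = np.random.default_rng(0)
        cands = []
        for i in range(100):
            t1 = rng.uniform(0, 20)
            cands.append(self._cand(i, t1, t1 + rng.uniform(0.1, 2.0)))
        t = 10.0
        d = build_scan_dictionary(cands, t, 0.01)
        brute = sum(1 for c in cands if c.rt_window[0] <= t <= c.rt_window[1])
        assert d.n_candidates == brute


class TestSolve:
    def test_single_envelope_identity(self):
        e = np.array([0.6, 0.3, 0.1])
        dic = _dict_from_envelopes({0: (np.array([10, 11, 12]), e)})
        frame = rasterize_sparse([10, 11, 12], [1.0], (3.0 * e)[:, None])
        res = solve_scan_activation(frame, dic)
        assert res.activation[0, 0] == pytest.approx(3.0, abs=1e-8)

    def test_disjoint_candidates_recovered_independently(self):
        dic = _dict_from_envelopes({
            0: (np.array([10, 11]), np.array([0.7, 0.3])),
            1: (np.array([50, 51]), np.array([0.6, 0.4])),
        })
        obs = np.zeros((4, 1))
        obs[:2, 0] = 2.0 * np.array([0.7, 0.3])
        obs[2:, 0] = 5.0 * np.array([0.6, 0.4])
        frame = rasterize_sparse([10, 11, 50, 51], [1.0], obs)
        res = solve_scan_activation(frame, dic)
        assert res.activation[:, 0] == pytest.approx([2.0, 5.0], abs=1e-10)

    def test_overlapping_isobars_match_grid_search_oracle(self):
        # two overlapping envelopes, noiseless mixture of (2, 5)
        e1 = np.array([0.5, 0.3, 0.2, 0.0])
        e2 = np.array([0.0, 0.4, 0.35, 0.25])
        bins = np.array([10, 11, 12, 13])
        dic = _dict_from_envelopes({0: (bins[e1 > 0], e1[e1 > 0]),
                                    1: (bins[e2 > 0], e2[e2 > 0])})
        s = 2.0 * e1 + 5.0 * e2
        frame = rasterize_sparse(bins, [1.0], s[:, None])
        res = solve_scan_activation(frame, dic)
        assert res.activation[:, 0] == pytest.approx([2.0, 5.0], abs=1e-6)
        # brute-force grid refinement oracle
        D = np.column_stack([e1, e2])
        best, arg = np.inf, None
        grid = np.linspace(0, 8, 81)
        for a in grid:
            r = s - a * e1
            b = max(0.0, float(e2 @ r) / float(e2 @ e2))
            err = np.sum((s - a * e1 - b * e2) ** 2)
            if err < best:
                best, arg = err, (a, b)
        for a in np.linspace(arg[0] - 0.1, arg[0] + 0.1, 201):
            r = s - a * e1
            b = max(0.0, float(e2 @ r) / float(e2 @ e2))
            err = np.sum((s - a * e1 - b * e2) ** 2)
            if err < best:
                best, arg = err, (a, b)
        assert res.activation[:, 0] == pytest.approx(arg, abs=1e-3)

    def test_zero_column_short_circuits(self):
        dic = _dict_from_envelopes({0: (np.array([10]), np.array([1.0]))})
        frame = rasterize_sparse([10], [1.0, 1.1], np.array([[5.0, 0.0]]))
        res = solve_scan_activation(frame, dic)
        assert res.activation[0, 1] == 0.0

    def test_nonnegativity_and_residual_optimality(self):
        rng = np.random.default_rng(4)
        bins = np.arange(30)
        envs = {}
        for cid in range(6):
            sub = np.sort(rng.choice(bins, 5, replace=False))
            envs[cid] = (sub, rng.uniform(0.1, 1.0, 5))
        dic = _dict_from_envelopes(envs)
        obs = rng.uniform(0, 10, (len(dic.bins), 2))
        frame = rasterize_sparse(dic.bins, [1.0, 1.1], obs)
        res = solve_scan_activation(frame, dic)
        assert (res.activation >= 0).all()
        D = dic.matrix.toarray()
        for col in range(2):
            a = res.activation[:, col]
            base = np.sum((obs[:, col] - D @ a) ** 2)
            for j in range(len(a)):
                for eps in (1e-4, -1e-4):
                    ap = a.copy()
                    ap[j] = max(0.0, ap[j] + eps)
                    assert np.sum((obs[:, col] - D @ ap) ** 2) >= base - 1e-9


class TestBlocks:
    def test_disjoint_gives_two_blocks(self):
        dic = _dict_from_envelopes({0: (np.array([1, 2]), np.array([1.0, 1.0])),
                                    1: (np.array([5, 6]), np.array([1.0, 1.0]))})
        assert len(partition_dictionary_blocks(dic)) == 2

    def test_overlap_chain_is_one_block(self):
        dic = _dict_from_envelopes({
            0: (np.array([1, 2]), np.array([1.0, 1.0])),
            1: (np.array([2, 3]), np.array([1.0, 1.0])),
            2: (np.array([3, 4]), np.array([1.0, 1.0]))})
        blocks = partition_dictionary_blocks(dic)
        assert len(blocks) == 1 and len(blocks[0][1]) == 3

    def test_blockwise_equals_monolithic_on_200_candidates(self):
        rng = np.random.default_rng(7)
        envs = {}
        for cid in range(200):
            start = int(rng.integers(0, 4000))
            k = int(rng.integers(2, 5))
            envs[cid] = (np.arange(start, start + k),
                         rng.uniform(0.05, 1.0, k))
        dic = _dict_from_envelopes(envs)
        obs = np.zeros((len(dic.bins), 3))
        truth = rng.uniform(0, 10, (200, 3))
        D = dic.matrix.toarray()
        obs = D @ truth + 0.0
        frame = rasterize_sparse(dic.bins, [1.0, 1.1, 1.2], obs)
        res = solve_scan_activation(frame, dic)
        for col in range(3):
            mono, _ = nnls(D, obs[:, col], maxiter=10 * D.shape[1])
            assert np.max(np.abs(res.activation[:, col] - mono)) < 1e-9


class TestAssemble:
    def _candidates(self):
        env = IsotopeEnvelope(np.array([[500.0, 1.0]]), 500.0, np.array([50000]))
        return [PrecursorCandidate(id=0, modified_sequence="S", charge=2,
                                   is_decoy=False, pair_id=0, envelope=env,
                                   rt_pred=1.0, rt_window=(0.95, 1.45),
                                   im_center=1.0, im_window=(0.95, 1.12))]

    def test_image_shape_follows_windows(self):
        cands = self._candidates()
        frames = [Ms1Frame(i, 0.9 + 0.1 * i, np.array([[500.0, 1.0, 10.0]]))
                  for i in range(8)]
        grid = np.array([0.90, 1.00, 1.05, 1.10, 1.20])
        cube = run_activation(frames, cands, 0.01, grid)
        img = assemble_and_slice(cube, cands)[0]
        n_scans = sum(1 for f in frames if 0.95 <= f.scan_time <= 1.45)
        assert img.matrix.shape == (n_scans, 3)  # grid values 1.00,1.05,1.10

    def test_empty_window_intersection_flagged(self):
        cands = self._candidates()
        cands[0].im_window = (2.0, 2.1)
        frames = [Ms1Frame(0, 1.0, np.array([[500.0, 1.0, 10.0]]))]
        cube = run_activation(frames, cands, 0.01, np.array([1.0]))
        img = assemble_and_slice(cube, cands)[0]
        assert img.flagged and img.matrix.shape == (1, 1) and img.matrix.sum() == 0

    def test_scan_order_independence(self):
        cands = self._candidates()
        frames = [Ms1Frame(i, 0.9 + 0.1 * i, np.array([[500.0, 1.0, 10.0 + i]]))
                  for i in range(5)]
        grid = np.array([1.0])
        cube1 = run_activation(frames, cands, 0.01, grid)
        cube2 = run_activation(frames[::-1][::-1], cands, 0.01, grid)
        img1 = assemble_and_slice(cube1, cands)[0]
        img2 = assemble_and_slice(cube2, cands)[0]
        assert np.array_equal(img1.matrix, img2.matrix)


class TestNaiveIntensity:
    def test_zero_image(self):
        img = PrecursorImage(0, np.zeros((3, 3)), np.arange(3), np.arange(3))
        assert naive_intensity(img) == 0.0

    def test_uniform_image(self):
        img = PrecursorImage(0, np.full((3, 3), 2.0), np.arange(3), np.arange(3))
        assert naive_intensity(img) == pytest.approx(18.0)

    def test_equals_elementwise_sum_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            m = rng.uniform(0, 5, (4, 6))
            img = PrecursorImage(0, m, np.arange(4), np.arange(6))
            assert naive_intensity(img) == pytest.approx(float(sum(map(sum, m))))


class TestCubeStore:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        images = [PrecursorImage(i, rng.uniform(0, 1, (3, 4)),
                                 np.linspace(0, 1, 3), np.linspace(0.9, 1.0, 4))
                  for i in range(5)]
        CubeStore.save(images, tmp_path / "cube", chunk_size=2)
        back = CubeStore.load(tmp_path / "cube")
        assert len(back) == 5
        for a, b in zip(images, sorted(back, key=lambda x: x.candidate_id)):
            assert np.array_equal(a.matrix, b.matrix)
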