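"""Scan-wise activation: per-scan linear deconvolution of MS1 frames.

Each MS1 frame is rasterized into a sparse (m/z bin x 1/K0 column) matrix
at 0.01 Th precision.  For every scan a scan-specific dictionary admits the
candidates whose RT window contains the scan time; each admitted candidate
contributes one column holding its binned isotope envelope.  Every 1/K0
column of the frame is then explained as a nonnegative linear combination
of dictionary columns (non-negative least squares; no sparsity penalty).
Because the objective separates over connected components of the
bin-candidate bipartite graph, a divide-and-conquer block solve is exactly
equivalent to the monolithic solve and is what we run.

Stacking per-scan activations along retention time yields the activation
cube; slicing it per candidate inside the candidate's RT/IM search windows
yields the precursor activation image handed to post-processing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import nnls
from scipy.sparse.csgraph import connected_components

from .io import Ms1Frame
from .library import PrecursorCandidate

logger = logging.getLogger("swaps")


def mz_bin(mz: np.ndarray | float, mz_bin_width: float) -> np.ndarray | int:
    """m/z -> integer bin index, floor convention."""
    return np.floor(np.asarray(mz) / mz_bin_width).astype(np.int64)


def build_im_grid(frames: Iterable[Ms1Frame]) -> np.ndarray:
    """Run-level 1/K0 grid: sorted union of observed values."""
    vals = [f.points[:, 1] for f in frames if len(f.points)]
    if not vals:
        return np.empty(0)
    return np.unique(np.concatenate(vals))


@dataclass
class SparseFrameMatrix:
    """One rasterized MS1 frame.

    ``bins`` are the sorted distinct m/z bin indices present; ``matrix`` is
    (len(bins) x len(im_grid)) sparse with summed intensity per cell.
    """

    bins: np.ndarray          # (r,) int64, sorted
    matrix: sp.csc_matrix     # (r, len(im_grid))
    im_grid: np.ndarray


def rasterize_frame(frame: Ms1Frame, mz_bin_width: float, im_grid: np.ndarray) -> SparseFrameMatrix:
    """Rasterize a point list onto (m/z bin, 1/K0 grid) cells, summing
    intensities of points sharing a cell.  Points whose 1/K0 is farther
    than half a grid step from the nearest grid value are dropped."""
    pts = frame.points
    if len(pts) == 0 or len(im_grid) == 0:
        return SparseFrameMatrix(np.empty(0, dtype=np.int64),
                                 sp.csc_matrix((0, len(im_grid))), im_grid)
    cols = np.searchsorted(im_grid, pts[:, 1])
    cols = np.clip(cols, 0, len(im_grid) - 1)
    left = np.clip(cols - 1, 0, len(im_grid) - 1)
    use_left = np.abs(im_grid[left] - pts[:, 1]) < np.abs(im_grid[cols] - pts[:, 1])
    cols = np.where(use_left, left, cols)
    if len(im_grid) > 1:
        half_step = np.diff(im_grid).min() / 2.0
        keep = np.abs(im_grid[cols] - pts[:, 1]) <= half_step + 1e-12
    else:
        keep = np.ones(len(pts), dtype=bool)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("stage=rasterize_frame frame=%d dropped_off_grid=%d", frame.frame_id, n_dropped)
    pts, cols = pts[keep], cols[keep]
    rows_all = mz_bin(pts[:, 0], mz_bin_width)
    bins = np.unique(rows_all)
    rows = np.searchsorted(bins, rows_all)
    mat = sp.coo_matrix((pts[:, 2], (rows, cols)), shape=(len(bins), len(im_grid))).tocsc()
    mat.sum_duplicates()
    return SparseFrameMatrix(bins=bins, matrix=mat, im_grid=im_grid)


@dataclass
class ScanDictionary:
    """Scan-specific dictionary: binned envelopes of the admitted candidates."""

    bins: np.ndarray            # (r,) int64, sorted union of envelope bins
    matrix: sp.csc_matrix       # (r, n_candidates)
    candidate_ids: np.ndarray   # (n_candidates,) int64

    @property
    def n_candidates(self) -> int:
        return len(self.candidate_ids)


def build_scan_dictionary(
    candidates: Sequence[PrecursorCandidate], scan_time: float, mz_bin_width: float
) -> ScanDictionary:
    """Admit every candidate with t1 <= scan_time <= t2 (inclusive) and
    populate its column with the binned envelope abundances."""
    admitted = [c for c in candidates if c.admitted(scan_time)]
    if not admitted:
        return ScanDictionary(np.empty(0, dtype=np.int64),
                              sp.csc_matrix((0, 0)), np.empty(0, dtype=np.int64))
    all_bins = np.unique(np.concatenate([c.envelope.bins for c in admitted]))
    rows, cols, vals = [], [], []
    for j, c in enumerate(admitted):
        r = np.searchsorted(all_bins, c.envelope.bins)
        rows.append(r)
        cols.append(np.full(len(r), j))
        vals.append(c.envelope.abundances)
    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(all_bins), len(admitted))).tocsc()
    return ScanDictionary(bins=all_bins, matrix=mat,
                          candidate_ids=np.array([c.id for c in admitted], dtype=np.int64))


def partition_dictionary_blocks(dic: ScanDictionary) -> list[tuple[np.ndarray, np.ndarray]]:
    """Connected components of the bin-candidate bipartite graph.

    Returns (bin-row-indices, candidate-column-indices) per block.  Solving
    blocks independently equals the monolithic solve exactly because the
    least-squares objective separates over components.
    """
    if dic.n_candidates == 0:
        return []
    adj = (dic.matrix.T @ dic.matrix) > 0
    n_comp, labels = connected_components(adj, directed=False)
    blocks = []
    for k in range(n_comp):
        cand_idx = np.where(labels == k)[0]
        sub = dic.matrix[:, cand_idx]
        bin_idx = np.unique(sub.nonzero()[0])
        blocks.append((bin_idx, cand_idx))
    return blocks


@dataclass
class ScanActivationResult:
    activation: np.ndarray        # (n_candidates, n_im_columns), >= 0
    column_residuals: np.ndarray  # (n_im_columns,) residual 2-norms


def solve_scan_activation(
    frame: SparseFrameMatrix, dic: ScanDictionary, tol: float = 1e-10
) -> ScanActivationResult:
    """Non-negative least squares per 1/K0 column.

    For each column s of the frame, minimizes ||s - D a||_2 over a >= 0,
    restricted to the dictionary's bin support (frame bins outside it only
    add a constant to the residual).  All-zero columns and columns with no
    overlapping support short-circuit to zero activation.
    """
    n_cols = frame.matrix.shape[1]
    act = np.zeros((dic.n_candidates, n_cols))
    resid = np.zeros(n_cols)
    if dic.n_candidates == 0 or n_cols == 0:
        return ScanActivationResult(act, resid)
    blocks = partition_dictionary_blocks(dic)
    frame_csr = frame.matrix.tocsr()
    for bin_idx, cand_idx in blocks:
        D = np.asarray(dic.matrix[bin_idx][:, cand_idx].todense())
        # observed intensities on this block's bins, per column
        frame_rows = np.searchsorted(frame.bins, dic.bins[bin_idx])
        valid = frame_rows < len(frame.bins)
        valid[valid] &= frame.bins[frame_rows[valid]] == dic.bins[bin_idx][valid]
        if not valid.any():
            continue
        obs = np.zeros((len(bin_idx), n_cols))
        obs[valid] = np.asarray(frame_csr[frame_rows[valid]].todense())
        nonzero_cols = np.where(obs.any(axis=0))[0]
        for col in nonzero_cols:
            coef, r = nnls(D, obs[:, col], maxiter=max(30, 3 * D.shape[1]))
            act[cand_idx, col] = coef
            resid[col] = np.hypot(resid[col], r)
    return ScanActivationResult(act, resid)


@dataclass
class PrecursorImage:
    """Activation image of one candidate inside its search windows."""

    candidate_id: int
    matrix: np.ndarray     # (m_p, n_p), >= 0
    rt_coords: np.ndarray  # (m_p,) minutes
    im_coords: np.ndarray  # (n_p,) 1/K0
    flagged: bool = False  # True when the window-grid intersection was empty


@dataclass
class ActivationCube:
    """Per-scan activation matrices stacked along retention time."""

    scan_times: np.ndarray                 # (n_scans,) minutes
    im_grid: np.ndarray                    # (n_cols,) 1/K0
    # candidate id -> {scan index: activation row over im_grid}
    rows: dict[int, dict[int, np.ndarray]] = field(default_factory=dict)

    def add_scan(self, scan_index: int, result: ScanActivationResult,
                 dic: ScanDictionary) -> None:
        for j, cid in enumerate(dic.candidate_ids):
            row = result.activation[j]
            self.rows.setdefault(int(cid), {})[scan_index] = row


def run_activation(
    frames: Sequence[Ms1Frame],
    candidates: Sequence[PrecursorCandidate],
    mz_bin_width: float,
    im_grid: np.ndarray | None = None,
) -> ActivationCube:
    """Rasterize all frames, solve each scan, and collect the cube.

    Scans are independent; processing order does not affect the result.
    """
    if im_grid is None:
        im_grid = build_im_grid(frames)
    cube = ActivationCube(scan_times=np.array([f.scan_time for f in frames]), im_grid=im_grid)
    for i, frame in enumerate(frames):
        sparse = rasterize_frame(frame, mz_bin_width, im_grid)
        dic = build_scan_dictionary(candidates, frame.scan_time, mz_bin_width)
        if dic.n_candidates == 0:
            continue
        cube.add_scan(i, solve_scan_activation(sparse, dic), dic)
    logger.info("stage=run_activation scans=%d candidates=%d grid=%d",
                len(frames), len(candidates), len(im_grid))
    return cube


def assemble_and_slice(
    cube: ActivationCube, candidates: Sequence[PrecursorCandidate]
) -> list[PrecursorImage]:
    """Slice the cube per candidate: rows are the scans inside the RT
    window (zero rows where the candidate was not admitted or had no
    signal), columns the IM grid values inside the 1/K0 window."""
    images: list[PrecursorImage] = []
    for c in candidates:
        t1, t2 = c.rt_window
        scan_idx = np.where((cube.scan_times >= t1) & (cube.scan_times <= t2))[0]
        lo, hi = c.im_window
        col_idx = np.where((cube.im_grid >= lo) & (cube.im_grid <= hi))[0]
        if len(scan_idx) == 0 or len(col_idx) == 0:
            images.append(PrecursorImage(c.id, np.zeros((1, 1)),
                                         np.array([c.rt_pred]), np.array([c.im_center]),
                                         flagged=True))
            continue
        mat = np.zeros((len(scan_idx), len(col_idx)))
        stored = cube.rows.get(c.id, {})
        for r, si in enumerate(scan_idx):
            row = stored.get(int(si))
            if row is not None:
                mat[r] = row[col_idx]
        images.append(PrecursorImage(c.id, mat, cube.scan_times[scan_idx],
                                     cube.im_grid[col_idx]))
    return images


def naive_intensity(image: PrecursorImage | np.ndarray) -> float:
    """Sum of all pixels: the unfiltered inferred intensity."""
    mat = image.matrix if isinstance(image, PrecursorImage) else np.asarray(image)
    return float(mat.sum())


class CubeStore:
    """Chunked on-disk store of precursor images, keyed by candidate id.

    Layout: ``<dir>/chunk_<k>.npz`` holding matrices and coordinate arrays
    under ``m<id>``/``rt<id>``/``im<id>`` keys, plus ``index.json`` mapping
    candidate id -> chunk file.
    """

    @staticmethod
    def save(images: Sequence[PrecursorImage], out_dir: str | Path, chunk_size: int = 256) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        index: dict[str, str] = {}
        for k in range(0, len(images), chunk_size):
            chunk = images[k:k + chunk_size]
            name = f"chunk_{k // chunk_size}.npz"
            arrays = {}
            for img in chunk:
                arrays[f"m{img.candidate_id}"] = img.matrix
                arrays[f"rt{img.candidate_id}"] = img.rt_coords
                arrays[f"im{img.candidate_id}"] = img.im_coords
                index[str(img.candidate_id)] = name
            np.savez_compressed(out_dir / name, **arrays)
        with open(out_dir / "index.json", "w") as fh:
            json.dump(index, fh)

    @staticmethod
    def load(out_dir: str | Path) -> list[PrecursorImage]:
        out_dir = Path(out_dir)
        with open(out_dir / "index.json") as fh:
            index = json.load(fh)
        by_chunk: dict[str, list[int]] = {}
        for cid, name in index.items():
            by_chunk.setdefault(name, []).append(int(cid))
        images = []
        for name, cids in sorted(by_chunk.items()):
            with np.load(out_dir / name) as data:
                for cid in sorted(cids):
                    images.append(PrecursorImage(cid, data[f"m{cid}"],
                                                 data[f"rt{cid}"], data[f"im{cid}"]))
        return images
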