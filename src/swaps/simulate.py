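"""Synthetic libraries and MS1 runs with known ground truth.

The generator emulates the data the pipeline consumes: evidence-style
libraries with realistic RT/IM/intensity distributions (median 1/K0
feature length ~0.072 with a 75th percentile of ~0.096; median elution
length ~0.16 min with a 75th percentile of ~0.21), and MS1 frame runs in
which each precursor deposits its total intensity as a truncated Gaussian
elution profile times a Gaussian ion-mobility profile times its isotope
envelope.  Noiseless runs conserve deposited intensity to the ledger by
construction.  The three-species mixture design (human/yeast/E. coli at
defined fractions per condition) drives the FDR and fold-change checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import EvidenceRecord, Ms1Frame, write_evidence_table, write_frames
from .library import compute_isotope_envelope, monoisotopic_mass, PROTON_MASS

logger = logging.getLogger("swaps")

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class MixtureSpec:
    """Species fractions per condition; each condition must sum to 1."""

    conditions: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for name, fracs in self.conditions.items():
            if abs(sum(fracs.values()) - 1.0) > 1e-9:
                raise ValueError(f"fractions of condition {name!r} must sum to 1")

    @classmethod
    def hye_default(cls) -> "MixtureSpec":
        """Mix A: 65% human / 30% yeast / 5% E. coli;
        Mix B: 65% human / 15% yeast / 20% E. coli."""
        return cls({
            "A": {"human": 0.65, "yeast": 0.30, "ecoli": 0.05},
            "B": {"human": 0.65, "yeast": 0.15, "ecoli": 0.20},
        })


@dataclass
class GroundTruthLedger:
    """Per-precursor generative truth, one row per (sequence, charge)."""

    table: pd.DataFrame  # modified_sequence, charge, total_intensity,
    #                      rt_apex, sigma_rt, im_center, sigma_im, species

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruthLedger":
        return cls(pd.read_csv(path, sep="\t"))


def _random_tryptic_sequence(rng: np.random.Generator) -> str:
    length = int(rng.integers(7, 31))
    body = "".join(rng.choice(list(_RESIDUES), size=length - 1))
    return body + rng.choice(["K", "R"])


def simulate_library(
    n: int,
    gradient_length: float = 30.0,
    seed: int = 0,
    mixture: MixtureSpec | None = None,
    condition: str = "A",
) -> tuple[list[EvidenceRecord], GroundTruthLedger]:
    """Draw ``n`` unique (sequence, charge) precursors.

    RT apexes are uniform over the gradient; 1/K0 centers correlate
    linearly with m/z and charge; log10 intensity is normal; elution and
    1/K0 feature lengths are lognormal with the medians/quartiles noted in
    the module docstring.  Species labels follow the mixture fractions of
    ``condition`` when a mixture is given.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[tuple[str, int]] = set()
    rows = []
    species_seq = None
    if mixture is not None:
        # largest-remainder proportional quotas, shuffled: every species is
        # represented at small n while counts stay inside multinomial bands
        fracs = mixture.conditions[condition]
        names = sorted(fracs)
        quotas = {s: int(np.floor(fracs[s] * n)) for s in names}
        remainders = sorted(names, key=lambda s: -(fracs[s] * n - quotas[s]))
        for s in remainders:
            if sum(quotas.values()) >= n:
                break
            quotas[s] += 1
        species_seq = [s for s in names for _ in range(quotas[s])]
        rng.shuffle(species_seq)
    while len(rows) < n:
        seq = _random_tryptic_sequence(rng)
        charge = int(rng.choice([2, 3, 4], p=[0.6, 0.3, 0.1]))
        if (seq, charge) in seen:
            continue
        seen.add((seq, charge))
        mz = (monoisotopic_mass(seq) + charge * PROTON_MASS) / charge
        im_center = float(np.clip(0.60 + 0.0006 * mz + 0.05 * (charge - 2)
                                  + rng.normal(0.0, 0.02), 0.75, 1.35))
        rt_apex = float(rng.uniform(0.0, 1.0)) * gradient_length
        # lognormal elution length: median 0.16 min, 75th pct 0.21 min
        rt_len = float(rng.lognormal(np.log(0.16), 0.403))
        # lognormal 1/K0 length: median 0.072, 75th pct 0.096
        im_len = float(rng.lognormal(np.log(0.072), 0.4265))
        intensity = float(10 ** rng.normal(5.5, 0.6))
        species = species_seq[len(rows)] if species_seq else "human"
        rows.append(dict(modified_sequence=seq, charge=charge,
                         total_intensity=intensity, rt_apex=rt_apex,
                         sigma_rt=rt_len / 4.0, im_center=im_center,
                         sigma_im=im_len / 4.0, species=species,
                         rt_len=rt_len, im_len=im_len))
    ledger = GroundTruthLedger(pd.DataFrame(rows).drop(columns=["rt_len", "im_len"]))
    records = [
        EvidenceRecord(
            modified_sequence=r["modified_sequence"], charge=r["charge"],
            rt_obs=r["rt_apex"],
            rt_start=r["rt_apex"] - r["rt_len"] / 2.0,
            rt_end=r["rt_apex"] + r["rt_len"] / 2.0,
            im_center=r["im_center"], im_length=r["im_len"],
            intensity=r["total_intensity"], species=r["species"],
            source="experiment",
        )
        for r in rows
    ]
    return records, ledger


def simulate_ms1_frames(
    ledger: GroundTruthLedger,
    frame_interval: float = 0.02,
    im_grid: np.ndarray | None = None,
    noise_points_per_frame: float = 0.0,
    noise_intensity_scale: float = 50.0,
    mz_bin_width: float = 0.01,
    isotope_min_abundance: float = 0.01,
    seed: int = 0,
    sigma_truncation: float = 4.0,
) -> list[Ms1Frame]:
    """Render a ledger into MS1 frames.

    Each precursor deposits ``total_intensity * w_rt(frame) * w_im(grid
    point) * envelope abundance`` at every (frame, 1/K0, isotope m/z)
    point, with the discrete Gaussian weights normalized inside a +/-4
    sigma truncation so the noiseless run conserves total intensity
    exactly.  Optional noise adds Poisson-count points per frame with
    uniform m/z and exponential intensity; noise never alters the ledger.
    """
    rng = np.random.default_rng(seed)
    tab = ledger.table
    if im_grid is None:
        im_grid = np.round(np.arange(0.75, 1.355, 0.005), 4)
    if len(tab) == 0:
        return []
    t_max = float((tab["rt_apex"] + sigma_truncation * tab["sigma_rt"]).max()) + frame_interval
    times = np.arange(0.0, t_max, frame_interval)
    points: list[list[np.ndarray]] = [[] for _ in times]
    mz_lo, mz_hi = np.inf, -np.inf
    for row in tab.itertuples(index=False):
        env = compute_isotope_envelope(row.modified_sequence, int(row.charge),
                                       isotope_min_abundance, mz_bin_width)
        mz_lo = min(mz_lo, env.mzs.min())
        mz_hi = max(mz_hi, env.mzs.max())
        w_t = np.exp(-0.5 * ((times - row.rt_apex) / row.sigma_rt) ** 2)
        w_t[np.abs(times - row.rt_apex) > sigma_truncation * row.sigma_rt] = 0.0
        if w_t.sum() == 0:
            continue
        w_t = w_t / w_t.sum()
        w_im = np.exp(-0.5 * ((im_grid - row.im_center) / row.sigma_im) ** 2)
        w_im[np.abs(im_grid - row.im_center) > sigma_truncation * row.sigma_im] = 0.0
        if w_im.sum() == 0:
            continue
        w_im = w_im / w_im.sum()
        im_idx = np.where(w_im > 0)[0]
        base = np.outer(w_im[im_idx], env.abundances) * row.total_intensity  # (im, iso)
        mzs = env.mzs
        for fi in np.where(w_t > 0)[0]:
            block = base * w_t[fi]
            pts = np.column_stack([
                np.tile(mzs, len(im_idx)),
                np.repeat(im_grid[im_idx], len(mzs)),
                block.ravel(),
            ])
            points[fi].append(pts)
    if noise_points_per_frame > 0 and np.isfinite(mz_lo):
        for fi in range(len(times)):
            k = int(rng.poisson(noise_points_per_frame))
            if k == 0:
                continue
            pts = np.column_stack([
                rng.uniform(mz_lo, mz_hi, size=k),
                rng.choice(im_grid, size=k),
                rng.exponential(noise_intensity_scale, size=k),
            ])
            points[fi].append(pts)
    frames = [
        Ms1Frame(fi, float(times[fi]),
                 np.vstack(points[fi]) if points[fi] else np.empty((0, 3)))
        for fi in range(len(times))
    ]
    logger.info("stage=simulate_ms1_frames frames=%d precursors=%d", len(frames), len(tab))
    return frames


def simulate_condition_pair(
    mixture: MixtureSpec,
    n: int,
    seed: int = 0,
    gradient_length: float = 4.0,
    conditions: tuple[str, str] = ("A", "B"),
    **frame_kwargs,
) -> dict[str, tuple[list[Ms1Frame], GroundTruthLedger]]:
    """Two runs sharing one precursor set, with per-species intensities
    scaled by the condition fractions (run ratios equal fraction ratios)."""
    records, ledger = simulate_library(n, gradient_length, seed, mixture,
                                       condition=conditions[0])
    base = mixture.conditions[conditions[0]]
    out: dict[str, tuple[list[Ms1Frame], GroundTruthLedger]] = {}
    for ci, cond in enumerate(conditions):
        fracs = mixture.conditions[cond]
        tab = ledger.table.copy()
        scale = tab["species"].map(lambda s: fracs[s] / base[s])
        tab["total_intensity"] = tab["total_intensity"] * scale
        led = GroundTruthLedger(tab)
        frames = simulate_ms1_frames(led, seed=seed + 1 + ci, **frame_kwargs)
        out[cond] = (frames, led)
    return out


def expected_box_activation(
    ledger: GroundTruthLedger,
    scan_times: np.ndarray,
    im_grid: np.ndarray,
    boxes: dict[tuple[str, int], tuple[float, float, float, float]],
    sigma_truncation: float = 4.0,
) -> dict[tuple[str, int], float]:
    """Ground-truth activation inside an (RT, 1/K0) box per precursor.

    For a noiseless run the scan-wise deconvolution recovers, at scan t
    and 1/K0 column v, exactly ``total_intensity * w_t(t) * w_im(v)`` with
    the generator's normalized truncated-Gaussian weights; summing those
    over the scans and grid values inside a box (e.g. label rectangle
    intersected with the search windows) gives the expected inferred
    intensity for any mask equal to that box.
    """
    out: dict[tuple[str, int], float] = {}
    scan_times = np.asarray(scan_times, dtype=float)
    im_grid = np.asarray(im_grid, dtype=float)
    for row in ledger.table.itertuples(index=False):
        key = (row.modified_sequence, int(row.charge))
        if key not in boxes:
            continue
        rt_lo, rt_hi, im_lo, im_hi = boxes[key]
        w_t = np.exp(-0.5 * ((scan_times - row.rt_apex) / row.sigma_rt) ** 2)
        w_t[np.abs(scan_times - row.rt_apex) > sigma_truncation * row.sigma_rt] = 0.0
        w_im = np.exp(-0.5 * ((im_grid - row.im_center) / row.sigma_im) ** 2)
        w_im[np.abs(im_grid - row.im_center) > sigma_truncation * row.sigma_im] = 0.0
        if w_t.sum() == 0 or w_im.sum() == 0:
            out[key] = 0.0
            continue
        w_t, w_im = w_t / w_t.sum(), w_im / w_im.sum()
        ft = w_t[(scan_times >= rt_lo) & (scan_times <= rt_hi)].sum()
        fv = w_im[(im_grid >= im_lo) & (im_grid <= im_hi)].sum()
        out[key] = float(row.total_intensity * ft * fv)
    return out


def bin_sharing_fraction(records: list[EvidenceRecord], mz_bin_width: float = 0.01,
                         isotope_min_abundance: float = 0.01) -> float:
    """Fraction of precursors whose envelope shares at least one m/z bin
    with another precursor's envelope (generator self-check)."""
    bins = [set(compute_isotope_envelope(r.modified_sequence, r.charge,
                                         isotope_min_abundance, mz_bin_width).bins.tolist())
            for r in records]
    shared = 0
    for i, bi in enumerate(bins):
        if any(i != j and bi & bj for j, bj in enumerate(bins)):
            shared += 1
    return shared / max(len(bins), 1)


def _shuffled_isobar(seq: str, rng: np.random.Generator) -> str | None:
    """A distinct permutation of the interior residues (same composition,
    hence identical envelope bins)."""
    body, cterm = list(seq[:-1]), seq[-1]
    for _ in range(20):
        perm = body.copy()
        rng.shuffle(perm)
        cand = "".join(perm) + cterm
        if cand != seq:
            return cand
    return None


def make_separable_model_pool(
    n_precursors: int = 50,
    seed: int = 0,
    image_size: int = 64,
    mz_bin_width: float = 0.01,
    rt_offset_bound: float = 0.15,
    delta_rt95: float = 0.35,
):
    """Separable fixture suite for the peak-selection and scoring models.

    Simulates a noiseless run whose RT prediction errors are uniformly
    bounded well inside the search windows, so every target image contains
    its full elution peak near the positive hint while decoy images carry
    no signal.  Returns a dict with segmentation pairs (3-channel input,
    resized label mask), scorer pairs (input, is-target label), images,
    candidates, and the ground-truth ledger.
    """
    from .library import CalibrationStats, assign_search_windows, generate_decoys, \
        load_mutation_map, compute_isotope_envelope, PrecursorCandidate
    from .activation import assemble_and_slice, build_im_grid, run_activation
    from . import models as models_mod
    from .pipeline import _competitor_hints, _label_rect

    rng = np.random.default_rng(seed)
    records, ledger = simulate_library(n_precursors, 4.0, seed)
    frames = simulate_ms1_frames(ledger, frame_interval=0.02,
                                 mz_bin_width=mz_bin_width, seed=seed + 1)
    candidates = []
    for i, rec in enumerate(records):
        env = compute_isotope_envelope(rec.modified_sequence, rec.charge,
                                       mz_bin_width=mz_bin_width)
        offset = float(rng.uniform(-rt_offset_bound, rt_offset_bound))
        candidates.append(PrecursorCandidate(
            id=i, modified_sequence=rec.modified_sequence, charge=rec.charge,
            is_decoy=False, pair_id=i, envelope=env,
            rt_pred=rec.rt_obs + offset, im_center=rec.im_center,
            library_intensity=rec.intensity, species=rec.species,
            rt_start_obs=rec.rt_start, rt_end_obs=rec.rt_end,
            im_length_obs=rec.im_length))
    stats = CalibrationStats(delta_rt95, 0.02,
                             float(np.percentile([r.im_length for r in records], 99.9)))
    targets = assign_search_windows(candidates, stats, im_mode="predicted")
    decoys = generate_decoys(targets, load_mutation_map(), mz_bin_width=mz_bin_width)
    grid = build_im_grid(frames)
    images = {}
    for pool in (targets, decoys):
        cube = run_activation(frames, pool, mz_bin_width, grid)
        for img in assemble_and_slice(cube, pool):
            images[img.candidate_id] = img
    seg_pairs, score_items = [], []
    for pool, label in ((targets, 1), (decoys, 0)):
        for c in pool:
            minput = models_mod.build_model_input(
                images[c.id], (c.rt_pred, c.im_center),
                _competitor_hints(c, pool, mz_bin_width), image_size=image_size)
            if label:
                mask = models_mod.rasterize_label(_label_rect(c), images[c.id], image_size)
                seg_pairs.append((minput, mask.resized.astype(float)))
            else:
                seg_pairs.append((minput, np.zeros((image_size, image_size))))
            score_items.append((minput, label, c.id))
    return {
        "segmentation_pairs": seg_pairs,
        "score_items": score_items,
        "images": images,
        "targets": targets,
        "decoys": decoys,
        "ledger": ledger,
        "stats": stats,
        "im_grid": grid,
        "frames": frames,
    }


_PRESETS = ("tiny", "mbr", "hye", "interference")


def write_fixture_bundle(out_dir: str | Path, preset: str = "tiny",
                         seed: int = 0, force: bool = False) -> dict[str, Path]:
    """Write a ready-to-run fixture bundle (libraries, frames, predictions,
    ledger, config) for one of the presets.

    tiny          -- <=50 precursors, short noiseless run; end-to-end smoke.
    mbr           -- experiment + reference libraries sharing precursors
                     (exercises the LOWESS alignment path).
    hye           -- three-species condition pair at defined fractions.
    interference  -- >=20% of precursors share m/z bins with an isobar.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {_PRESETS}")
    out_dir = Path(out_dir).resolve()  # configs must work from any cwd
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty (use force=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}

    gradient = 4.0
    frame_kwargs = dict(frame_interval=0.02, mz_bin_width=0.01)
    config = RunConfig(
        random_seed=seed,
        image_size=64, unet_depth=3, unet_base_channels=8,
        epochs=30, patience=8, batch_size=16,
        im_window_mode="predicted",
    )

    def write_run(records, ledger, tag="", noise=0.0, frame_seed=seed):
        name = f"frames{tag}.tsv"
        frames = simulate_ms1_frames(ledger, noise_points_per_frame=noise,
                                     seed=frame_seed, **frame_kwargs)
        write_frames(frames, out_dir / name)
        write_evidence_table(records, out_dir / f"experiment_library{tag}.tsv")
        ledger.write(out_dir / f"ledger{tag}.tsv")
        paths[f"frames{tag}"] = out_dir / name
        paths[f"experiment_library{tag}"] = out_dir / f"experiment_library{tag}.tsv"
        paths[f"ledger{tag}"] = out_dir / f"ledger{tag}.tsv"
        return frames

    def write_predictions(ledger, tag="", rt_sigma=0.2, im_sigma=0.015):
        # prediction errors sized so delta_rt95 (~0.4 min) clearly exceeds
        # the median elution length, mirroring the partially-predicted
        # library regime where search windows dwarf elution peaks
        tab = ledger.table
        prng = np.random.default_rng(seed + 97)
        df = pd.DataFrame({
            "modified_sequence": tab["modified_sequence"],
            "charge": tab["charge"],
            "rt_pred": tab["rt_apex"] + prng.normal(0.0, rt_sigma, len(tab)),
            "im_pred": tab["im_center"] + prng.normal(0.0, im_sigma, len(tab)),
        })
        df.to_csv(out_dir / f"predictions{tag}.tsv", sep="\t", index=False)
        paths[f"predictions{tag}"] = out_dir / f"predictions{tag}.tsv"

    if preset == "tiny":
        records, ledger = simulate_library(40, gradient, seed)
        write_run(records, ledger)
        write_predictions(ledger)
        config.experiment_library = str(out_dir / "experiment_library.tsv")
        config.frames = str(out_dir / "frames.tsv")
        config.predictions = str(out_dir / "predictions.tsv")
    elif preset == "interference":
        records, ledger = simulate_library(30, gradient, seed)
        tab = ledger.table
        extra_rows, extra_records = [], []
        for i in range(0, len(tab), 3):   # every third precursor gets an isobar
            row = tab.iloc[i]
            twin = _shuffled_isobar(row.modified_sequence, rng)
            if twin is None:
                continue
            r = row.copy()
            r["modified_sequence"] = twin
            r["im_center"] = float(np.clip(row.im_center + 0.05, 0.76, 1.34))
            r["rt_apex"] = row.rt_apex + 0.05
            extra_rows.append(r)
            src = records[i]
            extra_records.append(EvidenceRecord(
                modified_sequence=twin, charge=src.charge,
                rt_obs=r["rt_apex"], rt_start=r["rt_apex"] - (src.rt_end - src.rt_start) / 2,
                rt_end=r["rt_apex"] + (src.rt_end - src.rt_start) / 2,
                im_center=r["im_center"], im_length=src.im_length,
                intensity=src.intensity, species=src.species, source="experiment"))
        ledger = GroundTruthLedger(pd.concat([tab, pd.DataFrame(extra_rows)],
                                             ignore_index=True))
        records = records + extra_records
        write_run(records, ledger)
        write_predictions(ledger)
        config.experiment_library = str(out_dir / "experiment_library.tsv")
        config.frames = str(out_dir / "frames.tsv")
        config.predictions = str(out_dir / "predictions.tsv")
    elif preset == "mbr":
        records, ledger = simulate_library(60, gradient, seed)
        # reference run: same peptides observed in a longer gradient (RT
        # scaled + shifted), plus extra reference-only precursors
        ref_records, _ = simulate_library(20, gradient, seed + 13)
        ref = []
        for r in records[:40] + ref_records:
            rt = r.rt_obs * 1.1 + 0.5
            ref.append(EvidenceRecord(
                modified_sequence=r.modified_sequence, charge=r.charge,
                rt_obs=rt, rt_start=rt - (r.rt_end - r.rt_start) / 2,
                rt_end=rt + (r.rt_end - r.rt_start) / 2,
                im_center=r.im_center, im_length=r.im_length,
                intensity=r.intensity * 0.8, species=r.species, source="reference"))
        write_evidence_table(ref, out_dir / "reference_library.tsv")
        paths["reference_library"] = out_dir / "reference_library.tsv"
        write_run(records, ledger)
        config.experiment_library = str(out_dir / "experiment_library.tsv")
        config.reference_library = str(out_dir / "reference_library.tsv")
        config.frames = str(out_dir / "frames.tsv")
        config.im_window_mode = "experimental"
    elif preset == "hye":
        mixture = MixtureSpec.hye_default()
        runs = simulate_condition_pair(mixture, n=60, seed=seed,
                                       gradient_length=gradient, **frame_kwargs)
        for cond, (frames, led) in runs.items():
            tag = f"_{cond}"
            write_frames(frames, out_dir / f"frames{tag}.tsv")
            paths[f"frames{tag}"] = out_dir / f"frames{tag}.tsv"
            led.write(out_dir / f"ledger{tag}.tsv")
            paths[f"ledger{tag}"] = out_dir / f"ledger{tag}.tsv"
            recs, _ = simulate_library(60, gradient, seed, mixture, condition="A")
            # evidence intensities reflect the condition's scaling; ledger
            # rows are in the same order as the simulated records
            for r, t in zip(recs, led.table["total_intensity"]):
                r.intensity = float(t)
            write_evidence_table(recs, out_dir / f"experiment_library{tag}.tsv")
            paths[f"experiment_library{tag}"] = out_dir / f"experiment_library{tag}.tsv"
            write_predictions(led, tag=tag)
        config.experiment_library = str(out_dir / "experiment_library_A.tsv")
        config.frames = str(out_dir / "frames_A.tsv")
        config.predictions = str(out_dir / "predictions_A.tsv")

    config.out_dir = str(out_dir)
    config.to_yaml(out_dir / "config.yaml")
    paths["config"] = out_dir / "config.yaml"
    logger.info("stage=write_fixture_bundle preset=%s out=%s files=%d",
                preset, out_dir, len(paths))
    return paths
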