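"""End-to-end orchestration: dictionary build -> scan-wise activation ->
peak selection & scoring -> post-processing and FDR control.

The stages mirror the method's flow: construct the target+decoy precursor
dictionary with calibrated search windows, deconvolute every MS1 scan,
slice per-precursor activation images, filter them with the segmentation
model (or oracle label rectangles / no mask, per ``mask_mode``), score
them, and run the fixed filter chain (intensity -> target-decoy
competition -> signal competition -> confidence threshold at the FDR cap).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fdr as fdr_mod
from . import models as models_mod
from .activation import (assemble_and_slice, build_im_grid, mz_bin,
                         naive_intensity, run_activation, PrecursorImage)
from .config import RunConfig
from .io import EvidenceRecord, read_evidence_table, read_frames, write_results
from .library import (CalibrationStats, PrecursorCandidate, assign_search_windows,
                      compute_isotope_envelope, generate_decoys, load_mutation_map,
                      lowess_rt_alignment, merge_libraries, read_prediction_table,
                      compute_calibration_stats, AlignmentError)

logger = logging.getLogger("swaps")


@dataclass
class Dictionary:
    targets: list[PrecursorCandidate]
    decoys: list[PrecursorCandidate]
    stats: CalibrationStats
    mode: str  # "predicted" | "aligned" | "exact"


def build_dictionary(
    experiment: list[EvidenceRecord],
    reference: list[EvidenceRecord],
    cfg: RunConfig,
    predictions: dict | None = None,
) -> Dictionary:
    """Merge libraries, attach RT/IM predictions, calibrate window widths
    on a seeded holdout of the experiment library, and generate decoys.

    RT predictions come from (in order of preference) an external
    prediction table, a LOWESS alignment of reference onto experiment RT
    over shared precursors, or — when neither exists — the library's own
    observed coordinates (exact-dictionary mode, whose windows are the
    observed RT/IM feature extents)."""
    merged = merge_libraries(experiment, reference)
    ref_rt = {(r.modified_sequence, r.charge): r.rt_obs for r in reference}
    ref_im = {(r.modified_sequence, r.charge): r.im_center for r in reference}
    exp_keys = {(r.modified_sequence, r.charge) for r in experiment}

    mode = "exact"
    mapping = None
    if predictions:
        mode = "predicted"
    else:
        shared = [k for k in exp_keys if k in ref_rt]
        if len(shared) >= 20:
            exp_rt = {(r.modified_sequence, r.charge): r.rt_obs for r in experiment}
            pairs = [(ref_rt[k], exp_rt[k]) for k in sorted(shared)]
            mapping = lowess_rt_alignment(pairs)
            mode = "aligned"

    candidates: list[PrecursorCandidate] = []
    for i, rec in enumerate(merged):
        key = (rec.modified_sequence, rec.charge)
        rt_pred, im_pred = np.nan, None
        if mode == "predicted":
            if key in predictions:
                rt_pred, im_pred = predictions[key]
        elif mode == "aligned":
            rt_pred = float(mapping(ref_rt[key])) if key in ref_rt else rec.rt_obs
        else:
            rt_pred = rec.rt_obs
        env = compute_isotope_envelope(rec.modified_sequence, rec.charge,
                                       cfg.isotope_min_abundance, cfg.mz_bin_width)
        im_center = rec.im_center
        if cfg.im_window_mode == "predicted" and im_pred is not None and key not in exp_keys:
            im_center = im_pred
        is_exp = key in exp_keys
        candidates.append(PrecursorCandidate(
            id=i, modified_sequence=rec.modified_sequence, charge=rec.charge,
            is_decoy=False, pair_id=i, envelope=env, rt_pred=rt_pred,
            im_center=im_center, source=rec.source,
            library_intensity=rec.intensity, species=rec.species,
            rt_start_obs=rec.rt_start if is_exp else None,
            rt_end_obs=rec.rt_end if is_exp else None,
            im_length_obs=rec.im_length if is_exp else None,
        ))

    # calibration on a seeded holdout of the experiment library
    rng = np.random.default_rng(cfg.sub_seed("calibration"))
    exp_cands = [c for c in candidates if (c.modified_sequence, c.charge) in exp_keys
                 and np.isfinite(c.rt_pred)]
    exp_rt_obs = {(r.modified_sequence, r.charge): r.rt_obs for r in experiment}
    exp_im_obs = {(r.modified_sequence, r.charge): r.im_center for r in experiment}
    exp_im_len = [r.im_length for r in experiment]
    if mode == "exact" or not exp_cands:
        stats = CalibrationStats(0.0, 0.0, float(np.percentile(exp_im_len, cfg.im_length_percentile))
                                 if exp_im_len else 0.0)
    else:
        n_hold = max(1, int(round(len(exp_cands) * cfg.rt_holdout_fraction)))
        hold = rng.choice(len(exp_cands), size=n_hold, replace=False)
        rt_pairs, im_pairs = [], []
        for idx in hold:
            c = exp_cands[idx]
            key = (c.modified_sequence, c.charge)
            rt_pairs.append((c.rt_pred, exp_rt_obs[key]))
            if mode == "predicted" and predictions and key in predictions \
                    and predictions[key][1] is not None:
                im_pairs.append((predictions[key][1], exp_im_obs[key]))
        stats = compute_calibration_stats(rt_pairs, im_pairs, exp_im_len,
                                          cfg.im_length_percentile)

    cross_delta = None
    if reference:
        shared = sorted(k for k in exp_keys if k in ref_im)
        if shared:
            cross_delta = float(np.percentile(
                [abs(ref_im[k] - exp_im_obs[k]) for k in shared], 95.0))

    if mode == "exact":
        # error-free library: windows are the observed feature extents
        targets = []
        for c in candidates:
            if c.rt_start_obs is None:
                continue
            c.rt_window = (c.rt_start_obs, c.rt_end_obs)
            half = (c.im_length_obs or 0.0) / 2.0
            c.im_window = (c.im_center - half, c.im_center + half)
            targets.append(c)
    else:
        targets = assign_search_windows(candidates, stats,
                                        im_mode=cfg.im_window_mode,
                                        cross_library_delta_im=cross_delta)
    mutation_map = load_mutation_map(cfg.mutation_map)
    decoys = generate_decoys(targets, mutation_map, mz_bin_width=cfg.mz_bin_width,
                             min_abundance=cfg.isotope_min_abundance)
    return Dictionary(targets=targets, decoys=decoys, stats=stats, mode=mode)


@dataclass
class PipelineResult:
    scored: list[fdr_mod.ScoredCandidate]
    fdr_table: fdr_mod.FdrTable
    stage_counts: dict[str, int]
    dictionary: Dictionary
    reports: dict = field(default_factory=dict)


def _label_rect(c: PrecursorCandidate) -> models_mod.LabelRect | None:
    if c.rt_start_obs is None or c.im_length_obs is None:
        return None
    half = c.im_length_obs / 2.0
    return models_mod.LabelRect(c.rt_start_obs, c.rt_end_obs,
                                c.im_center - half, c.im_center + half)


def _competitor_hints(c: PrecursorCandidate, pool: list[PrecursorCandidate],
                      mz_bin_width: float) -> list[tuple[float, float]]:
    my_bin = mz_bin(c.envelope.mono_mz, mz_bin_width)
    hints = []
    for o in pool:
        if o.id == c.id or mz_bin(o.envelope.mono_mz, mz_bin_width) != my_bin:
            continue
        if (o.rt_window[0] <= c.rt_window[1] and o.rt_window[1] >= c.rt_window[0]
                and o.im_window[0] <= c.im_window[1] and o.im_window[1] >= c.im_window[0]):
            hints.append((o.rt_pred, o.im_center))
    return hints


def execute(cfg: RunConfig) -> PipelineResult:
    """Run the full pipeline per the configuration and return everything."""
    stage_counts: dict[str, int] = {}
    experiment = read_evidence_table(cfg.experiment_library, "experiment")
    reference = (read_evidence_table(cfg.reference_library, "reference")
                 if cfg.reference_library else [])
    predictions = read_prediction_table(cfg.predictions) if cfg.predictions else None
    dictionary = build_dictionary(experiment, reference, cfg, predictions)
    targets, decoys = dictionary.targets, dictionary.decoys
    stage_counts["targets"] = len(targets)
    stage_counts["decoys"] = len(decoys)

    frames = read_frames(cfg.frames)
    im_grid = build_im_grid(frames)
    # targets and decoys go through separate searches
    images: dict[int, PrecursorImage] = {}
    for pool in (targets, decoys):
        if not pool:
            continue
        cube = run_activation(frames, pool, cfg.mz_bin_width, im_grid)
        for img in assemble_and_slice(cube, pool):
            images[img.candidate_id] = img

    by_id = {c.id: c for c in targets + decoys}
    inputs: dict[int, models_mod.ModelInput] = {}
    for pool in (targets, decoys):
        for c in pool:
            img = images[c.id]
            inputs[c.id] = models_mod.build_model_input(
                img, (c.rt_pred, c.im_center),
                _competitor_hints(c, pool, cfg.mz_bin_width),
                image_size=cfg.image_size)

    labeled = [c for c in targets if _label_rect(c) is not None]
    decoys_of_labeled = [d for d in decoys if d.pair_id in {c.id for c in labeled}]

    masks: dict[int, np.ndarray] = {}
    intensities: dict[int, float] = {}
    seg_prob: dict[int, np.ndarray] = {}
    reports: dict = {}

    if cfg.mask_mode == "model":
        pool = []
        for c in labeled:
            mask = models_mod.rasterize_label(_label_rect(c), images[c.id], cfg.image_size)
            pool.append((inputs[c.id], mask.resized.astype(float)))
        for d in decoys_of_labeled:
            pool.append((inputs[d.id], np.zeros((cfg.image_size, cfg.image_size))))
        seg_model, seg_report = models_mod.train_segmentation(pool, cfg)
        reports["segmentation"] = seg_report
        for cid, minput in inputs.items():
            mask, intensity = models_mod.predict_mask_and_intensity(
                seg_model, minput, images[cid], cfg.mask_probability_threshold)
            masks[cid] = mask.native
            intensities[cid] = intensity
            seg_prob[cid] = models_mod.segmentation_probability(seg_model, minput)
        score_pool = [(models_mod.ModelInput(np.concatenate(
            [inputs[c.id].channels, seg_prob[c.id][None]]), c.id), 1) for c in labeled]
        score_pool += [(models_mod.ModelInput(np.concatenate(
            [inputs[d.id].channels, seg_prob[d.id][None]]), d.id), 0) for d in decoys_of_labeled]
        scorer, score_report = models_mod.train_scorer(score_pool, cfg)
        reports["scorer"] = score_report
        confidences = {
            cid: models_mod.confidence_score(
                scorer, models_mod.ModelInput(np.concatenate(
                    [inputs[cid].channels, seg_prob[cid][None]]), cid))
            for cid in inputs
        }
    elif cfg.mask_mode == "oracle":
        for cid, minput in inputs.items():
            c = by_id[cid]
            rect = _label_rect(c)
            img = images[cid]
            if rect is not None:
                mask = models_mod.rasterize_label(rect, img, cfg.image_size)
                masks[cid] = mask.native
                intensities[cid] = float(img.matrix[mask.native].sum())
            else:
                masks[cid] = np.ones(img.matrix.shape, dtype=bool)
                intensities[cid] = naive_intensity(img)
        confidences = {cid: 0.5 for cid in inputs}
    elif cfg.mask_mode == "full":
        for cid in inputs:
            img = images[cid]
            masks[cid] = np.ones(img.matrix.shape, dtype=bool)
            intensities[cid] = naive_intensity(img)
        confidences = {cid: 0.5 for cid in inputs}
    else:
        raise ValueError(f"unknown mask_mode {cfg.mask_mode!r}")

    scored = []
    for c in targets + decoys:
        scored.append(fdr_mod.ScoredCandidate(
            candidate_id=c.id, pair_id=c.pair_id, is_decoy=c.is_decoy,
            inferred_intensity=max(intensities[c.id], 0.0),
            confidence=float(np.clip(confidences[c.id], 0.0, 1.0)),
            mono_bin=int(mz_bin(c.envelope.mono_mz, cfg.mz_bin_width)),
            rt_pred=c.rt_pred, im_center=c.im_center,
            modified_sequence=c.modified_sequence, charge=c.charge,
            species=c.species, source=c.source))
    stage_counts["scored"] = len(scored)

    survivors = fdr_mod.intensity_filter(scored, cfg.intensity_threshold)
    stage_counts["intensity_filter"] = len(survivors)
    if cfg.mask_mode == "model":
        survivors = fdr_mod.target_decoy_competition(survivors)
        stage_counts["tdc"] = len(survivors)
        survivors = fdr_mod.signal_competition(survivors, dictionary.stats,
                                               cfg.signal_competition_log10_tol)
        stage_counts["signal_competition"] = len(survivors)
    else:
        # oracle/full modes skip confidence-based competition (no scorer)
        for c in survivors:
            c.passed_tdc = c.passed_signal_competition = True
        stage_counts["tdc"] = stage_counts["signal_competition"] = len(survivors)
    table = fdr_mod.fdr_sweep(survivors, cfg.max_fdr)
    accepted = [c for c in survivors if c.confidence >= table.chosen_threshold]
    stage_counts["accepted"] = len(accepted)
    logger.info("stage=pipeline counts=%s", stage_counts)
    return PipelineResult(scored=scored, fdr_table=table, stage_counts=stage_counts,
                          dictionary=dictionary, reports=reports)


def run_pipeline(config_path: str | Path) -> int:
    """CLI entry: run the configured pipeline, write results; returns the
    process exit status (0 on success)."""
    stage = "configuration"
    try:
        cfg = RunConfig.from_yaml(config_path)
        stage = "pipeline"
        result = execute(cfg)
        stage = "write_results"
        out_dir = Path(cfg.out_dir or ".")
        out_dir.mkdir(parents=True, exist_ok=True)
        write_results(result.scored, result.fdr_table, out_dir / "results")
        with open(out_dir / "stage_counts.json", "w") as fh:
            json.dump(result.stage_counts, fh, indent=1)
        return 0
    except Exception:
        logger.exception("pipeline aborted at stage %s", stage)
        return 1
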