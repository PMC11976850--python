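"""Post-processing chain and target-decoy FDR control.

Fixed filter order: inferred-intensity floor, target-decoy competition
(TDC), signal competition, then a confidence-score threshold chosen so the
estimated FDR (N_decoy / N_target among survivors) stays below the
configured maximum.  Each stage only removes candidates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import CalibrationStats

logger = logging.getLogger("swaps")


@dataclass
class ScoredCandidate:
    """A candidate after activation, peak selection and scoring."""

    candidate_id: int
    pair_id: int
    is_decoy: bool
    inferred_intensity: float
    confidence: float
    mono_bin: int
    rt_pred: float
    im_center: float
    modified_sequence: str = ""
    charge: int = 0
    species: str | None = None
    source: str = "experiment"
    passed_intensity_filter: bool = False
    passed_tdc: bool = False
    passed_signal_competition: bool = False
    fdr_at_score: float = math.nan

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")
        if self.inferred_intensity < 0:
            raise ValueError("inferred intensity must be nonnegative")


def intensity_filter(candidates: list[ScoredCandidate],
                     threshold: float = 100.0) -> list[ScoredCandidate]:
    """Remove candidates whose inferred intensity is strictly below the
    threshold (a candidate exactly at the threshold is kept)."""
    kept = []
    for c in candidates:
        c.passed_intensity_filter = c.inferred_intensity >= threshold
        if c.passed_intensity_filter:
            kept.append(c)
    logger.info("stage=intensity_filter in=%d out=%d", len(candidates), len(kept))
    return kept


def target_decoy_competition(candidates: list[ScoredCandidate]) -> list[ScoredCandidate]:
    """Within each surviving target/decoy pair keep only the higher-
    confidence member; exact ties keep the decoy (conservative).  Unpaired
    survivors pass unopposed."""
    by_pair: dict[int, list[ScoredCandidate]] = {}
    for c in candidates:
        by_pair.setdefault(c.pair_id, []).append(c)
    kept = []
    for pair in by_pair.values():
        targets = [c for c in pair if not c.is_decoy]
        decoys = [c for c in pair if c.is_decoy]
        if targets and decoys:
            t, d = targets[0], decoys[0]
            winner = t if t.confidence > d.confidence else d
            winner.passed_tdc = True
            kept.append(winner)
        else:
            for c in pair:
                c.passed_tdc = True
                kept.append(c)
    kept.sort(key=lambda c: c.candidate_id)
    logger.info("stage=target_decoy_competition in=%d out=%d", len(candidates), len(kept))
    return kept


def signal_competition(
    candidates: list[ScoredCandidate],
    stats: CalibrationStats,
    log10_tol: float = 0.01,
) -> list[ScoredCandidate]:
    """Resolve candidates claiming the same MS1 feature.

    Two candidates compete when they share the monoisotopic m/z bin and
    their predicted RT and 1/K0 differ by less than 2 x delta_rt95 and
    2 x delta_im95.  If their log10 inferred intensities differ by less
    than ``log10_tol`` the lower-confidence member is removed.  Competitor
    pairs are processed in descending order of the pair's maximum
    confidence, and a removed candidate cannot eliminate others.
    """
    pairs = []
    by_bin: dict[int, list[int]] = {}
    for i, c in enumerate(candidates):
        by_bin.setdefault(c.mono_bin, []).append(i)
    for idxs in by_bin.values():
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                ci, cj = candidates[idxs[a]], candidates[idxs[b]]
                if (abs(ci.rt_pred - cj.rt_pred) < 2 * stats.delta_rt95
                        and abs(ci.im_center - cj.im_center) < 2 * stats.delta_im95
                        and abs(math.log10(max(ci.inferred_intensity, 1e-12))
                                - math.log10(max(cj.inferred_intensity, 1e-12))) < log10_tol):
                    pairs.append((max(ci.confidence, cj.confidence), idxs[a], idxs[b]))
    removed: set[int] = set()
    for _, i, j in sorted(pairs, key=lambda t: -t[0]):
        if i in removed or j in removed:
            continue
        loser = i if candidates[i].confidence <= candidates[j].confidence else j
        removed.add(loser)
    kept = []
    for i, c in enumerate(candidates):
        c.passed_signal_competition = i not in removed
        if c.passed_signal_competition:
            kept.append(c)
    logger.info("stage=signal_competition in=%d out=%d pairs=%d",
                len(candidates), len(kept), len(pairs))
    return kept


def compute_fdr(n_target: int, n_decoy: int) -> float:
    """FDR = N_decoy / N_target; NaN (with a warning) when no targets."""
    if n_target < 0 or n_decoy < 0:
        raise ValueError("counts must be nonnegative")
    if n_target == 0:
        logger.warning("FDR undefined: zero surviving targets")
        return math.nan
    return n_decoy / n_target


@dataclass
class FdrTable:
    """Threshold sweep: one row per distinct confidence value, descending."""

    thresholds: np.ndarray
    n_target: np.ndarray
    n_decoy: np.ndarray
    fdr: np.ndarray
    chosen_threshold: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "n_target": self.n_target,
            "n_decoy": self.n_decoy,
            "fdr": self.fdr,
        })

    def q_values(self) -> np.ndarray:
        """Optional monotonized (cumulative-minimum) FDR column.

        This q-value-style column is an extension beyond the plain
        per-threshold estimate; the reported FDR itself is never
        monotonized.
        """
        return np.minimum.accumulate(np.nan_to_num(self.fdr, nan=np.inf))


def fdr_sweep(candidates: list[ScoredCandidate], max_fdr: float = 0.20) -> FdrTable:
    """Sweep confidence thresholds over the distinct score values and pick
    the smallest threshold whose FDR is at or below ``max_fdr`` (0 when no
    thresholding is needed)."""
    conf = np.array([c.confidence for c in candidates])
    is_decoy = np.array([c.is_decoy for c in candidates], dtype=bool)
    thresholds = np.unique(conf)[::-1]
    n_t = np.array([int(((conf >= t) & ~is_decoy).sum()) for t in thresholds])
    n_d = np.array([int(((conf >= t) & is_decoy).sum()) for t in thresholds])
    fdr = np.array([compute_fdr(t, d) for t, d in zip(n_t, n_d)])
    if len(thresholds) and not math.isnan(fdr[-1]) and fdr[-1] <= max_fdr:
        chosen = 0.0  # already below the cap with every candidate accepted
    else:
        ok = [t for t, f in zip(thresholds, fdr) if not math.isnan(f) and f <= max_fdr]
        chosen = float(min(ok)) if ok else (float(thresholds[0]) if len(thresholds) else 0.0)
    table = FdrTable(thresholds, n_t, n_d, fdr, chosen_threshold=chosen)
    for c in candidates:
        pos = np.searchsorted(-thresholds, -c.confidence)
        c.fdr_at_score = float(fdr[pos]) if pos < len(fdr) else math.nan
    logger.info("stage=fdr_sweep candidates=%d thresholds=%d chosen=%.3f",
                len(candidates), len(thresholds), chosen)
    return table
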