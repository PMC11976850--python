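"""Precursor dictionary construction.

The dictionary defines the search space: every candidate is a (modified
sequence, charge) pair with a binned isotope envelope, a retention-time
search window derived from a predicted RT plus a calibrated 95th-percentile
error, and an ion-mobility (1/K0) window derived from the candidate's 1/K0
center plus a calibrated delta and half the 99.9th-percentile feature
length.  Decoy candidates are produced by a two-round residue-mutation rule
and compete with their paired targets downstream.

Modified sequences use bracketed notation, e.g. ``PEPTM[ox]IDE`` or
``[ac]MPEPTIDEK``; supported modifications are carbamidomethyl-C (``cam``),
oxidation-M (``ox``) and N-terminal acetylation (``ac``).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from pyteomics import mass as _ptmass
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from ._isotopes import isotope_distribution
from .io import EvidenceRecord

logger = logging.getLogger("swaps")

PROTON_MASS = 1.00727646677  # Da

#: Monoisotopic elemental composition of the 20 standard residues.
RESIDUE_COMPOSITIONS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

#: Elemental deltas of the supported modifications.
MODIFICATION_DELTAS: dict[str, dict[str, int]] = {
    "cam": {"C": 2, "H": 3, "N": 1, "O": 1},  # carbamidomethyl (on C)
    "ox": {"O": 1},                            # oxidation (on M)
    "ac": {"C": 2, "H": 2, "O": 1},            # N-terminal acetylation
}

_TOKEN_RE = re.compile(r"([A-Z])(\[[a-z]+\])?")


def parse_modified_sequence(modified_sequence: str) -> tuple[str | None, list[tuple[str, str | None]]]:
    """Split a bracketed modified sequence into an optional N-terminal
    modification and a list of (residue, modification) tokens."""
    seq = modified_sequence
    nterm = None
    m = re.match(r"^\[([a-z]+)\]", seq)
    if m:
        nterm = m.group(1)
        seq = seq[m.end():]
    tokens: list[tuple[str, str | None]] = []
    pos = 0
    for m in _TOKEN_RE.finditer(seq):
        if m.start() != pos:
            raise ValueError(f"cannot parse modified sequence {modified_sequence!r}")
        tokens.append((m.group(1), m.group(2)[1:-1] if m.group(2) else None))
        pos = m.end()
    if pos != len(seq) or not tokens:
        raise ValueError(f"cannot parse modified sequence {modified_sequence!r}")
    return nterm, tokens


def format_modified_sequence(nterm: str | None, tokens: Sequence[tuple[str, str | None]]) -> str:
    head = f"[{nterm}]" if nterm else ""
    return head + "".join(r + (f"[{m}]" if m else "") for r, m in tokens)


def peptide_composition(modified_sequence: str) -> dict[str, int]:
    """Elemental composition of a modified peptide: residue compositions
    plus one water plus modification deltas."""
    nterm, tokens = parse_modified_sequence(modified_sequence)
    comp: Counter[str] = Counter({"H": 2, "O": 1})
    mods = ([nterm] if nterm else []) + [m for _, m in tokens if m]
    for residue, _ in tokens:
        if residue not in RESIDUE_COMPOSITIONS:
            raise ValueError(f"unknown residue {residue!r} in {modified_sequence!r}")
        comp.update(RESIDUE_COMPOSITIONS[residue])
    for mod in mods:
        if mod not in MODIFICATION_DELTAS:
            raise ValueError(f"unknown modification {mod!r} in {modified_sequence!r}")
        comp.update(MODIFICATION_DELTAS[mod])
    return dict(comp)


def monoisotopic_mass(modified_sequence: str) -> float:
    """Neutral monoisotopic mass in Da."""
    return _ptmass.calculate_mass(composition=_ptmass.Composition(peptide_composition(modified_sequence)))


@dataclass
class IsotopeEnvelope:
    """Binned isotope envelope of one precursor ion.

    Abundances are probabilities of the total isotopologue distribution,
    aggregated per m/z bin; peaks below the abundance threshold are dropped
    and the remainder is deliberately NOT renormalized, so activation
    coefficients stay comparable across candidates.
    """

    peaks: np.ndarray        # (n, 2): m/z, abundance, sorted by m/z
    mono_mz: float
    bins: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def mzs(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def abundances(self) -> np.ndarray:
        return self.peaks[:, 1]

    def total_abundance(self) -> float:
        return float(self.peaks[:, 1].sum())


def compute_isotope_envelope(
    modified_sequence: str,
    charge: int,
    min_abundance: float = 0.01,
    mz_bin_width: float = 0.01,
) -> IsotopeEnvelope:
    """Enumerate fine-structure isotopologues, aggregate them into the run's
    m/z bins and keep every bin with total abundance above ``min_abundance``.

    The envelope's ``mono_mz`` is (neutral monoisotopic mass + charge *
    proton mass) / charge.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    comp = peptide_composition(modified_sequence)
    mono_mass = _ptmass.calculate_mass(composition=_ptmass.Composition(comp))
    mono_mz = (mono_mass + charge * PROTON_MASS) / charge
    shifts, probs = isotope_distribution(comp, prune=min(1e-5, min_abundance / 100.0))
    mzs = (mono_mass + shifts + charge * PROTON_MASS) / charge
    by_bin: dict[int, list[tuple[float, float]]] = {}
    for mz, abundance in zip(mzs, probs):
        b = int(np.floor(mz / mz_bin_width))
        by_bin.setdefault(b, []).append((mz, abundance))
    rows = []
    for b, entries in by_bin.items():
        ab = sum(a for _, a in entries)
        if ab > min_abundance:
            mz_mean = sum(m * a for m, a in entries) / ab
            rows.append((b, mz_mean, ab))
    rows.sort()
    bins = np.array([r[0] for r in rows], dtype=np.int64)
    peaks = np.array([[r[1], r[2]] for r in rows], dtype=float).reshape(-1, 2)
    return IsotopeEnvelope(peaks=peaks, mono_mz=mono_mz, bins=bins)


@dataclass
class CalibrationStats:
    """Calibrated search-window parameters.

    delta_rt95 / delta_im95 are 95th percentiles of absolute prediction
    error on the held-out fraction of the experiment library;
    im_length_q999 is the 99.9th percentile of observed 1/K0 feature
    lengths.  Percentiles use linear interpolation between order statistics.
    """

    delta_rt95: float      # minutes
    delta_im95: float      # 1/K0 units
    im_length_q999: float  # 1/K0 units

    def __post_init__(self) -> None:
        if min(self.delta_rt95, self.delta_im95, self.im_length_q999) < 0:
            raise ValueError("calibration statistics must be nonnegative")


def compute_calibration_stats(
    pred_vs_obs_rt: Sequence[tuple[float, float]],
    pred_vs_obs_im: Sequence[tuple[float, float]],
    im_lengths: Sequence[float],
    im_length_percentile: float = 99.9,
) -> CalibrationStats:
    if not len(pred_vs_obs_rt) or not len(im_lengths):
        raise ValueError("calibration requires nonempty holdout data")
    rt = np.asarray(pred_vs_obs_rt, dtype=float)
    drt = float(np.percentile(np.abs(rt[:, 0] - rt[:, 1]), 95.0))
    if len(pred_vs_obs_im):
        im = np.asarray(pred_vs_obs_im, dtype=float)
        dim = float(np.percentile(np.abs(im[:, 0] - im[:, 1]), 95.0))
    else:
        dim = 0.0
    q = float(np.percentile(np.asarray(im_lengths, dtype=float), im_length_percentile))
    return CalibrationStats(delta_rt95=drt, delta_im95=dim, im_length_q999=q)


@dataclass
class PrecursorCandidate:
    """One dictionary entry (target or decoy)."""

    id: int
    modified_sequence: str
    charge: int
    is_decoy: bool
    pair_id: int                       # links a decoy to its source target
    envelope: IsotopeEnvelope | None = None
    rt_pred: float = np.nan            # minutes
    rt_window: tuple[float, float] = (np.nan, np.nan)
    im_center: float = np.nan          # 1/K0
    im_window: tuple[float, float] = (np.nan, np.nan)
    source: str = "experiment"         # experiment | reference | both
    library_intensity: float = 0.0
    species: str | None = None
    # experimental coordinates for label rectangles, when known
    rt_start_obs: float | None = None
    rt_end_obs: float | None = None
    im_length_obs: float | None = None

    @property
    def mono_bin(self) -> int:
        if self.envelope is None:
            raise ValueError("candidate has no envelope")
        return int(self.envelope.bins[0]) if len(self.envelope.bins) else -1

    def admitted(self, scan_time: float) -> bool:
        t1, t2 = self.rt_window
        return t1 <= scan_time <= t2


_SOURCE_ORDER = {"experiment": 0, "reference": 1}


def merge_libraries(
    experiment: Sequence[EvidenceRecord],
    reference: Sequence[EvidenceRecord] = (),
) -> list[EvidenceRecord]:
    """Merge the experiment and reference libraries into a deduplicated
    candidate list, unique on (modified sequence, charge).

    Among duplicates the record with the highest observed intensity
    survives (ties: experiment source first, then lexicographically
    smallest source tag); its ``source`` is set to ``both`` when the key
    occurs in both libraries.  1/K0 is more reproducible than RT, so for
    shared keys the surviving record carries the reference library's 1/K0
    center and length, while RT coordinates come from the experiment
    library when available (they define segmentation labels).
    """
    groups: dict[tuple[str, int], list[EvidenceRecord]] = {}
    for rec in list(experiment) + list(reference):
        groups.setdefault((rec.modified_sequence, rec.charge), []).append(rec)
    merged: list[EvidenceRecord] = []
    for key in sorted(groups):
        recs = groups[key]
        winner = min(recs, key=lambda r: (-r.intensity, _SOURCE_ORDER.get(r.source, 9), r.source))
        sources = {r.source for r in recs}
        out = replace(winner)
        out.source = "both" if {"experiment", "reference"} <= sources else winner.source
        exp = [r for r in recs if r.source == "experiment"]
        ref = [r for r in recs if r.source == "reference"]
        if ref:
            best_ref = max(ref, key=lambda r: r.intensity)
            out.im_center, out.im_length = best_ref.im_center, best_ref.im_length
        if exp:
            best_exp = max(exp, key=lambda r: r.intensity)
            out.rt_obs, out.rt_start, out.rt_end = best_exp.rt_obs, best_exp.rt_start, best_exp.rt_end
        out.intensity = max(r.intensity for r in recs)
        merged.append(out)
    logger.info("stage=merge_libraries in=%d out=%d", sum(len(v) for v in groups.values()), len(merged))
    return merged


class AlignmentError(ValueError):
    pass


class LowessAlignment:
    """Monotone-smooth RT mapping fitted on common precursors."""

    def __init__(self, x: np.ndarray, y_fit: np.ndarray, residuals: np.ndarray):
        self._x = x
        self._y = y_fit
        self.residuals = residuals

    def __call__(self, rt: np.ndarray | float) -> np.ndarray | float:
        return np.interp(rt, self._x, self._y)


def lowess_rt_alignment(
    common: Sequence[tuple[float, float]], frac: float = 0.3
) -> LowessAlignment:
    """Fit a LOWESS mapping source-run RT -> target-run RT on the RT pairs
    of commonly identified precursors (>= 20 required)."""
    if len(common) < 20:
        raise AlignmentError(
            "need >= 20 common precursors for LOWESS alignment; "
            "supply an external RT prediction table instead")
    arr = np.asarray(common, dtype=float)
    fitted = _sm_lowess(arr[:, 1], arr[:, 0], frac=frac, return_sorted=True)
    x, y = fitted[:, 0], fitted[:, 1]
    # collapse duplicate x for single-valued interpolation
    ux, idx = np.unique(x, return_index=True)
    uy = np.array([y[x == v].mean() for v in ux]) if len(ux) < len(x) else y[idx]
    residuals = mapping_residuals(arr, ux, uy)
    return LowessAlignment(ux, uy, residuals=residuals)


def mapping_residuals(arr: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.interp(arr[:, 0], x, y) - arr[:, 1]


def assign_search_windows(
    candidates: Sequence[PrecursorCandidate],
    stats: CalibrationStats,
    im_mode: str = "experimental",
    cross_library_delta_im: float | None = None,
) -> list[PrecursorCandidate]:
    """Attach RT and 1/K0 search windows.

    RT window: rt_pred +/- delta_rt95.  1/K0 window: im_center +/-
    (delta_im + im_length_q999 / 2), where delta_im is the predicted-vs-
    observed 95th percentile in ``predicted`` mode and the cross-library
    delta (falling back to delta_im95) in ``experimental`` mode.
    Candidates without a finite rt_pred or im_center are excluded and
    counted.
    """
    if im_mode not in ("experimental", "predicted"):
        raise ValueError(f"unknown im_mode {im_mode!r}")
    delta_im = stats.delta_im95 if im_mode == "predicted" else (
        cross_library_delta_im if cross_library_delta_im is not None else stats.delta_im95)
    half_im = delta_im + stats.im_length_q999 / 2.0
    out, n_excluded = [], 0
    for c in candidates:
        if not (np.isfinite(c.rt_pred) and np.isfinite(c.im_center)):
            n_excluded += 1
            continue
        c = replace(c,
                    rt_window=(c.rt_pred - stats.delta_rt95, c.rt_pred + stats.delta_rt95),
                    im_window=(c.im_center - half_im, c.im_center + half_im))
        out.append(c)
    logger.info("stage=assign_search_windows in=%d out=%d excluded=%d",
                len(candidates), len(out), n_excluded)
    return out


def load_mutation_map(path: str | Path | None = None) -> dict[str, str]:
    """Load a residue mutation map from a two-column TSV; defaults to the
    fixed map shipped with the package."""
    if path is None:
        path = Path(__file__).parent / "data" / "mutation_map.tsv"
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("from"):
                continue
            src, dst = line.split("\t")
            mapping[src] = dst
    missing = set(RESIDUE_COMPOSITIONS) - set(mapping)
    if missing:
        raise ValueError(f"mutation map is not total; missing {sorted(missing)}")
    return mapping


def generate_decoys(
    targets: Sequence[PrecursorCandidate],
    mutation_map: dict[str, str],
    closeness_tol: float | None = None,
    mz_bin_width: float = 0.01,
    min_abundance: float = 0.01,
) -> list[PrecursorCandidate]:
    """Generate sequence-mutation decoys.

    Round 1 mutates the second and the second-to-last residue.  If the
    round-1 decoy's monoisotopic mass is within ``closeness_tol`` of the
    target's (default: mz_bin_width * charge, i.e. the envelopes would land
    in the same bins), the third-to-last residue is mutated too.  Decoys
    whose sequence equals any target sequence are removed.  A mutated
    residue loses any residue-level modification it carried.  Targets
    shorter than 4 residues get no decoy.
    """
    target_seqs = {t.modified_sequence for t in targets}
    next_id = (max((t.id for t in targets), default=-1)) + 1
    decoys: list[PrecursorCandidate] = []
    n_short = n_collision = 0
    for t in targets:
        nterm, tokens = parse_modified_sequence(t.modified_sequence)
        if len(tokens) < 4:
            n_short += 1
            continue

        def mutate(tok: list[tuple[str, str | None]], pos: int) -> list[tuple[str, str | None]]:
            tok = list(tok)
            tok[pos] = (mutation_map[tok[pos][0]], None)
            return tok

        d_tokens = mutate(mutate(tokens, 1), len(tokens) - 2)
        d_seq = format_modified_sequence(nterm, d_tokens)
        tol = closeness_tol if closeness_tol is not None else mz_bin_width * t.charge
        if abs(monoisotopic_mass(d_seq) - monoisotopic_mass(t.modified_sequence)) < tol:
            d_tokens = mutate(d_tokens, len(d_tokens) - 3)
            d_seq = format_modified_sequence(nterm, d_tokens)
        if d_seq in target_seqs:
            n_collision += 1
            continue
        envelope = compute_isotope_envelope(d_seq, t.charge, min_abundance, mz_bin_width)
        decoys.append(PrecursorCandidate(
            id=next_id, modified_sequence=d_seq, charge=t.charge, is_decoy=True,
            pair_id=t.id, envelope=envelope, rt_pred=t.rt_pred, rt_window=t.rt_window,
            im_center=t.im_center, im_window=t.im_window, source=t.source,
            library_intensity=t.library_intensity, species=t.species))
        next_id += 1
    logger.info("stage=generate_decoys targets=%d decoys=%d short=%d collisions=%d",
                len(targets), len(decoys), n_short, n_collision)
    return decoys


def read_prediction_table(path: str | Path) -> dict[tuple[str, int], tuple[float, float | None]]:
    """Read an external RT(/IM) prediction TSV keyed by (sequence, charge)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    preds: dict[tuple[str, int], tuple[float, float | None]] = {}
    has_im = "im_pred" in df.columns
    for row in df.itertuples(index=False):
        preds[(str(row.modified_sequence), int(row.charge))] = (
            float(row.rt_pred), float(row.im_pred) if has_im else None)
    return preds
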