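"""Run configuration.

Every tunable constant of the pipeline lives in :class:`RunConfig`, a flat
key-value document that can be round-tripped through YAML.  Defaults are the
pipeline's standard operating values: 0.01 Th m/z bins, an inferred-intensity
floor of 100, a confidence-score threshold of 0.2 and a maximum FDR of 20%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class RunConfig:
    """Flat configuration for a full run.

    All randomness flows from ``random_seed``; stages derive named sub-seeds
    through :meth:`sub_seed` so that individual stages are reproducible in
    isolation.
    """

    # rasterization / dictionary
    mz_bin_width: float = 0.01          # Thomson
    isotope_min_abundance: float = 0.01  # fraction of total isotopologue prob.
    im_length_percentile: float = 99.9   # percentile of 1/K0 feature lengths
    rt_holdout_fraction: float = 0.10    # held out for calibration stats

    # post-processing
    intensity_threshold: float = 100.0
    confidence_threshold: float = 0.2
    max_fdr: float = 0.20
    signal_competition_log10_tol: float = 0.01

    # model input / networks
    image_size: int = 258
    unet_depth: int = 6
    unet_base_channels: int = 32
    mask_probability_threshold: float = 0.5

    # training
    epochs: int = 100
    patience: int = 10
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    loss_weights: tuple[float, float, float] = (1.0, 4.0, 1.0)  # BCE, dice, focal
    batch_size: int = 32
    max_learning_rate: float = 1e-3

    # reproducibility
    random_seed: int = 0

    # pipeline file references (used by the CLI orchestration)
    experiment_library: str | None = None
    reference_library: str | None = None
    frames: str | None = None
    predictions: str | None = None
    mutation_map: str | None = None
    out_dir: str | None = None
    # peak selection mode: "model" trains/applies the segmentation network,
    # "oracle" uses label rectangles (exact-dictionary style), "full" keeps
    # every pixel (naive summation).
    mask_mode: str = "model"
    im_window_mode: str = "experimental"  # or "predicted"

    def __post_init__(self) -> None:
        for name in ("mz_bin_width", "isotope_min_abundance", "intensity_threshold",
                     "confidence_threshold", "max_fdr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rt_holdout_fraction",):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        self.split = tuple(self.split)  # type: ignore[assignment]
        self.loss_weights = tuple(self.loss_weights)  # type: ignore[assignment]

    def sub_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from ``random_seed``.

        Kept below 2**31 so it is usable anywhere a C long is expected.
        """
        h = 2166136261
        for ch in stage.encode():
            h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
        return (self.random_seed * 1000003 + h) % (2**31 - 1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["split"] = list(self.split)
        doc["loss_weights"] = list(self.loss_weights)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
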