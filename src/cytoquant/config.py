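"""Pipeline configuration.

Every numeric constant of the analysis lives here exactly once; modules take
these values as arguments and never hard-code them.  The defaults mirror the
acquisition and analysis settings the pipeline was designed around: 30 nm
pixels, a 2-pixel (60 nm) structure-tensor integration scale, a 10 %
coherency/energy exclusion, Laplacian-of-Gaussian scales of 3-7 px with a
0.25 response threshold, a 1 µm cell-boundary exclusion zone, and 99.9th
percentile intensity normalization for the adhesion channel.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger("cytoquant")


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis pipeline.

    Attributes
    ----------
    pixel_size_nm : float
        Physical pixel size in nanometres (default 30 nm).
    sigma_gradient_px : float
        Derivative-of-Gaussian scale for image gradients, pixels.
    sigma_tensor_px : float
        Gaussian integration scale for structure-tensor smoothing, pixels
        (default 2 px = 60 nm at 30 nm/px).
    exclusion_fraction : float
        Pixels with coherency or energy below this fraction of the per-image
        (masked) maximum are excluded from histograms and dominant-orientation
        averaging.
    n_bins : int
        Number of 1-degree bins over the 180-degree axial domain.
    log_sigmas_px : tuple of float
        Laplacian-of-Gaussian scale series for adhesion-site detection.
    log_threshold : float
        Minimum scale-normalized LoG response for an adhesion detection.
    border_exclusion_um : float
        Detections closer than this to the cell boundary are discarded.
    percentile : float
        Upper percentile for adhesion-channel intensity normalization.
    seed : int
        Base seed for any stochastic step (synthetic data generation).
    out_dir : str
        Default output directory for pipeline runs.
    """

    pixel_size_nm: float = 30.0
    sigma_gradient_px: float = 1.0
    sigma_tensor_px: float = 2.0
    exclusion_fraction: float = 0.10
    n_bins: int = 180
    log_sigmas_px: tuple[float, ...] = (3.0, 4.0, 5.0, 6.0, 7.0)
    log_threshold: float = 0.25
    border_exclusion_um: float = 1.0
    percentile: float = 99.9
    seed: int = 0
    out_dir: str = "cytoquant_out"

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.sigma_gradient_px <= 0 or self.sigma_tensor_px <= 0:
            raise ValueError("Gaussian scales must be positive")
        if not 0 <= self.exclusion_fraction < 1:
            raise ValueError("exclusion_fraction must be in [0, 1)")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if len(self.log_sigmas_px) == 0:
            raise ValueError("log_sigmas_px must be non-empty")
        self.log_sigmas_px = tuple(float(s) for s in self.log_sigmas_px)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["log_sigmas_px"] = list(self.log_sigmas_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)
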