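"""Analysis configuration: one structured (YAML) file, logged when resolved."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the synchrony pipeline.

    Attributes
    ----------
    fs
        RR resampling rate (Hz).
    n_target
        Length of every analyzed RR series (samples).
    tau
        Embedding delay (samples).
    m
        Embedding dimension.  ``None`` selects it per series by false
        nearest neighbors and takes the study-level maximum.
    fnn_cutoff, r_tol, m_max
        False-nearest-neighbor fraction cutoff, distance-ratio
        tolerance, and largest dimension tried.
    epsilon
        Recurrence threshold.  With ``epsilon_mode='global_frac'``
        (default) it is a fraction of the dataset-level phase-space
        diameter of the segment (one fixed cut for every pair, as a
        cross-condition comparison requires); ``'max_frac'`` scales by
        each pair's own maximal distance; ``'absolute'`` uses raw
        normalized (per-dimension RMS, z-scored-amplitude) distance
        units.
    norm
        Distance norm for recurrence: ``rms`` (Euclidean scaled by
        1/sqrt(m); default), ``euclidean`` or ``max``.
    l_min, v_min
        Minimum diagonal / vertical line length counted as a line.
    entropy_normalized
        Divide line entropy by log(#distinct lengths).  Off by
        default: the raw Shannon entropy tracks shared dynamics
        monotonically, whereas the normalizer itself grows with line
        diversity and can invert group contrasts.
    epsilon_grid
        Optional candidate grid: when set, the pipeline selects a
        threshold per in-group pair (see ``threshold_mode``), fixes the
        study-level threshold at their mean, and ignores ``epsilon``.
    threshold_mode
        Data-driven threshold rule: SD of the diagonal line-length
        distribution (``diag_sd``) or of the binary matrix (``matrix_sd``).
    question
        Rating item used for convergence scoring.
    seed
        Seed for the out-group pairing draw.
    """

    fs: float = 4.0
    n_target: int = 430
    tau: int = 1
    m: int | None = 11
    fnn_cutoff: float = 0.1
    r_tol: float = 10.0
    m_max: int = 15
    epsilon: float = 0.2
    epsilon_grid: list[float] | None = None
    epsilon_mode: str = "absolute"
    norm: str = "rms"
    l_min: int = 2
    v_min: int = 2
    entropy_normalized: bool = False
    threshold_mode: str = "diag_sd"
    question: str = "emotional_intensity_performance"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.m is not None and self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 < self.fnn_cutoff < 1:
            raise ValueError("fnn_cutoff must be in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.epsilon_mode not in ("absolute", "max_frac", "global_frac"):
            raise ValueError(f"unknown epsilon_mode {self.epsilon_mode!r}")
        if self.norm not in ("rms", "euclidean", "max"):
            raise ValueError(f"unknown norm {self.norm!r}")
        if self.l_min < 2 or self.v_min < 2:
            raise ValueError("l_min and v_min must be >= 2")
        if self.threshold_mode not in ("diag_sd", "matrix_sd"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def log_resolved(self) -> None:
        """Log the fully resolved configuration (every run should call this)."""
        logger.info("resolved configuration: %s", self.to_dict())
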