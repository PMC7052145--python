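"""End-to-end pipeline: tachograms + ratings -> synchrony and correlations."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io
from .behavior import (
    ConvergenceScore,
    convergence_scores,
    correlate_intensity,
    correlate_metrics,
    correlation_table,
)
from .config import AnalysisConfig
from .crqa import select_threshold_global, select_threshold_pair
from .embedding import delay_embed, fnn_dimension, global_dimension, zscore
from .groups import (
    ParticipantSynchrony,
    build_pairings,
    group_contrast,
    participant_synchrony,
    synchrony_table,
)
from .manifest import RatingTable, SessionManifest, Tachogram
from .preprocess import extract_segments

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: AnalysisConfig
    m: int        # embedding dimension actually used
    epsilon: float  # recurrence threshold actually used
    synchrony: list[ParticipantSynchrony]
    synchrony_df: pd.DataFrame
    contrast_df: pd.DataFrame
    scores: list[ConvergenceScore]
    convergence_correlations: dict[str, pd.DataFrame]  # by group type
    intensity_correlations: dict[str, pd.DataFrame]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_metrics_table(self.synchrony_df, out / "synchrony.csv")
        self.contrast_df.to_csv(out / "contrast.csv", index=False,
                                float_format=io.FLOAT_FORMAT)
        scores = pd.DataFrame(
            [{"participant_id": s.participant, "group_type": s.group_type,
              "score": s.score} for s in self.scores]
        )
        scores.to_csv(out / "convergence_scores.csv", index=False,
                      float_format=io.FLOAT_FORMAT)
        for group, df in self.convergence_correlations.items():
            df.to_csv(out / f"convergence_correlations_{group}.csv",
                      index=False, float_format=io.FLOAT_FORMAT)
        for group, df in self.intensity_correlations.items():
            df.to_csv(out / f"intensity_correlations_{group}.csv",
                      index=False, float_format=io.FLOAT_FORMAT)


def _select_epsilon(manifest, series, config, m) -> float:
    """Paper-style threshold: select per in-group pair, fix the mean."""
    pair_eps = []
    embeddings = {}

    def emb(key):
        if key not in embeddings:
            embeddings[key] = delay_embed(zscore(series[key].values),
                                          m, config.tau)
        return embeddings[key]

    for quartet in manifest.quartets:
        members = manifest.quartet_members(quartet)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                for segment in sorted({seg for (_, seg) in series}):
                    if (a, segment) not in series or (b, segment) not in series:
                        continue
                    pair_eps.append(
                        select_threshold_pair(
                            emb((a, segment)), emb((b, segment)),
                            config.epsilon_grid, norm=config.norm,
                            mode=config.threshold_mode, l_min=config.l_min,
                        )
                    )
    return select_threshold_global(pair_eps)


def run_pipeline(
    manifest: SessionManifest,
    tachograms: list[Tachogram],
    ratings: RatingTable,
    config: AnalysisConfig | None = None,
) -> PipelineResult:
    """Run preprocessing, CRQA, group contrast and correlations."""
    config = config or AnalysisConfig()
    config.log_resolved()
    manifest.validate()
    ratings.validate()

    series = extract_segments(manifest, tachograms,
                              fs=config.fs, n_target=config.n_target)
    if not series:
        raise ValueError("no usable participant series")

    if config.m is not None:
        m = config.m
    else:
        dims = {
            key: fnn_dimension(s.values, m_max=config.m_max, tau=config.tau,
                               r_tol=config.r_tol,
                               fnn_cutoff=config.fnn_cutoff)
            for key, s in series.items()
        }
        m = global_dimension(dims)
        logger.info("study-level embedding dimension from FNN: m = %d", m)

    if config.epsilon_grid is not None:
        epsilon = _select_epsilon(manifest, series, config, m)
        logger.info("study-level threshold from grid selection: %.4g", epsilon)
    else:
        epsilon = config.epsilon

    pairings = build_pairings(manifest, seed=config.seed)
    synchrony = participant_synchrony(
        pairings, series, epsilon=epsilon, m=m, tau=config.tau,
        norm=config.norm, l_min=config.l_min, v_min=config.v_min,
        entropy_normalized=config.entropy_normalized,
        epsilon_mode=config.epsilon_mode,
    )
    contrast = group_contrast(synchrony)
    scores = convergence_scores(ratings, pairings, question=config.question)

    convergence_corr = {}
    intensity_corr = {}
    for group in ("in", "out"):
        convergence_corr[group] = correlation_table(
            correlate_metrics(scores, synchrony, group_type=group)
        )
        intensity_corr[group] = correlation_table(
            correlate_intensity(ratings, synchrony, group_type=group,
                                question=config.question)
        )

    return PipelineResult(
        config=config, m=m, epsilon=epsilon, synchrony=synchrony,
        synchrony_df=synchrony_table(synchrony),
        contrast_df=contrast, scores=scores,
        convergence_correlations=convergence_corr,
        intensity_correlations=intensity_corr,
    )
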