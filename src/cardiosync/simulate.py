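"""Synthetic quartet sessions: coupled RR tachograms plus Likert ratings.

The generator emulates the study design — quartets of four spectators
watching two monologues with three two-minute rests — so the whole
pipeline can be exercised offline.  Within-quartet cardiac coupling is
produced by an additive shared slow driver: the instantaneous RR of
participant p in quartet q is

    RR_p(t) = rr_mean + rr_sd * (c_q * s_q(t) + c_out * g(t) + b * u_p(t))
              + white noise,

where s_q is a band-limited (0.04-0.15 Hz) unit-variance driver shared
by the quartet, g a driver shared by everyone (off by default: out-group
members attended different sessions), u_p an individual band-limited
process, and the white term per-beat measurement noise.  R-peak times
are obtained by cumulatively summing instantaneous RR (integral-pulse
scheme).

Ratings are drawn around a quartet-level mean with dispersion shrinking
to zero as ``rating_agreement`` approaches one.  Optionally the
per-quartet coupling gain and rating agreement are tied together
(``link_ratings_to_coupling``), which induces the negative
synchrony-convergence dependence the correlation stage should recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .manifest import (
    RATING_QUESTIONS,
    RatingTable,
    SessionManifest,
    Tachogram,
)

MONOLOGUE_LABELS = ("AUG10", "NOV20")

_SIM_FS = 4.0  # driver sampling rate (Hz)
_PAD_S = 12.0  # driver/tachogram padding beyond the session (s)

#: diagnostic: per-quartet (coupling gain, rating agreement) of the last
#: simulate_session call; useful when validating recovery pipelines
_last_quartet_state: dict[str, tuple[float, float]] = {}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic run.

    Defaults mirror the analyzed study: 11 quartets, two-minute rests,
    performance durations ~ Normal(5.41 min, 1.26 min) truncated at
    4 min, RR around 0.85 s.
    """

    n_quartets: int = 11
    coupling_in: float = 1.0       # shared-driver gain for quartet members
    coupling_out: float = 0.0      # gain of a driver linking all quartets
    driver_band: tuple[float, float] = (0.04, 0.15)      # Hz
    individual_band: tuple[float, float] = (0.04, 0.15)  # Hz; matches the
    # driver band so coupling changes cross-correlation, not the
    # marginal spectrum of any series
    individual_gain: float = 0.35
    noise_frac: float = 0.04       # per-beat white noise as a fraction of
    # the modelled slow-signal SD (~2 ms at default amplitudes, the
    # order of R-peak jitter at 1 kHz ECG sampling); keeping the noise
    # SHARE fixed keeps every series' marginal spectrum independent of
    # the coupling gain
    rr_mean: float = 0.85          # s
    rr_sd: float = 0.05            # s, scale of the modelled variability
    rest_s: float = 120.0
    performance_mean_s: float = 5.41 * 60.0
    performance_sd_s: float = 1.26 * 60.0
    performance_min_s: float = 240.0
    fixed_performance_s: float | None = None  # override: fixed duration
    rating_agreement: float = 0.7  # in [0, 1]; 1 = identical ratings
    rating_sigma: float = 2.0      # dispersion scale of ratings
    link_ratings_to_coupling: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_quartets < 1:
            raise ValueError("n_quartets must be >= 1")
        if self.coupling_in < 0 or self.coupling_out < 0:
            raise ValueError("coupling gains must be >= 0")
        if not 0.4 < self.rr_mean < 1.5:
            raise ValueError("rr_mean must be in (0.4, 1.5) s")
        if not 0.0 <= self.rating_agreement <= 1.0:
            raise ValueError("rating_agreement must be in [0, 1]")
        if self.rr_sd < 0 or self.noise_frac < 0:
            raise ValueError("rr_sd and noise_frac must be >= 0")


def _band_limited(band: tuple[float, float], n: int,
                  generator: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian process sampled at _SIM_FS."""
    white = generator.standard_normal(n)
    nyq = _SIM_FS / 2.0
    sos = butter(2, [band[0] / nyq, band[1] / nyq], btype="bandpass",
                 output="sos")
    x = sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _truncated_duration(cfg: SimulationConfig,
                        rng: np.random.Generator) -> float:
    if cfg.fixed_performance_s is not None:
        return float(cfg.fixed_performance_s)
    for _ in range(1000):
        d = rng.normal(cfg.performance_mean_s, cfg.performance_sd_s)
        if d >= cfg.performance_min_s:
            return float(d)
    return float(cfg.performance_min_s)


def _r_peaks(signal: np.ndarray, t0: float, t_end: float,
             noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Integral-pulse R-peak times from an instantaneous-RR signal."""
    sig = signal.tolist()
    n_sig = len(sig)
    max_beats = int((t_end - t0) / 0.3) + 4
    noise = rng.normal(0.0, noise_sd, size=max_beats).tolist() if noise_sd > 0 \
        else [0.0] * max_beats
    peaks = []
    t = t0
    k = 0
    while t < t_end and k < max_beats:
        peaks.append(t)
        x = (t - t0) * _SIM_FS
        i = int(x)
        if i >= n_sig - 1:
            i = n_sig - 2
        rr = sig[i] + (sig[i + 1] - sig[i]) * (x - i) + noise[k]
        # physiological guard rails: keep RR inside the plausibility window
        if rr < 0.3:
            rr = 0.3
        elif rr > 2.5:
            rr = 2.5
        t += rr
        k += 1
    return np.asarray(peaks)


def simulate_session(
    config: SimulationConfig,
) -> tuple[SessionManifest, list[Tachogram], RatingTable]:
    """Generate one full multi-quartet session, deterministically from seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_q = config.n_quartets
    # longest possible session, used as a common driver-grid length
    max_perf = (config.fixed_performance_s
                if config.fixed_performance_s is not None
                else config.performance_mean_s + 5 * config.performance_sd_s)
    t_max = 3 * config.rest_s + 2 * max_perf + _PAD_S
    n_grid = int((t_max + _PAD_S) * _SIM_FS) + 2

    global_driver = _band_limited(config.driver_band, n_grid, rng)
    _last_quartet_state.clear()

    participants: list[str] = []
    quartet_of: dict[str, str] = {}
    segments: dict[str, dict[str, tuple[float, float]]] = {}
    monologue_order: dict[str, tuple[str, str]] = {}
    tachograms: list[Tachogram] = []
    rating_rows: list[dict] = []

    for qi in range(n_q):
        qid = f"q{qi + 1:02d}"
        d1 = _truncated_duration(config, rng)
        d2 = _truncated_duration(config, rng)
        rest = config.rest_s
        m1_start, m1_end = rest, rest + d1
        rest1_end = m1_end + rest
        m2_start, m2_end = rest1_end, rest1_end + d2
        t_end = m2_end + rest
        windows = {
            "baseline": (0.0, rest),
            "m1_T1": (m1_start, m1_start + rest),
            "m1_T2": (m1_end - rest, m1_end),
            "rest1": (m1_end, rest1_end),
            "m2_T1": (m2_start, m2_start + rest),
            "m2_T2": (m2_end - rest, m2_end),
            "rest2": (m2_end, t_end),
        }
        order = (MONOLOGUE_LABELS if qi % 2 == 0
                 else MONOLOGUE_LABELS[::-1])
        monologue_order[qid] = order

        if config.link_ratings_to_coupling:
            # latent "collective engagement" e ~ U(0, 1) of the quartet,
            # expressed behaviorally as rating agreement and
            # physiologically as the share rho of each member's modelled
            # variance carried by the shared driver; the residual share
            # shrinks geometrically in e (recurrence responds roughly
            # linearly to log residual share)
            engagement = rng.uniform(0.0, 1.0)
            rho = 1.0 - 0.4 * 0.02 ** engagement
            c_q = (config.coupling_in * config.individual_gain
                   * np.sqrt(rho / (1.0 - rho)))
            agreement = engagement
        else:
            c_q = config.coupling_in
            agreement = config.rating_agreement

        _last_quartet_state[qid] = (float(c_q), float(agreement))
        shared = _band_limited(config.driver_band, n_grid, rng)

        member_ids = [f"{qid}p{pi + 1}" for pi in range(4)]
        # beats oversample fast-heart-rate stretches, biasing the beat
        # average of RR by -var/mean; compensate so the tachogram mean
        # matches rr_mean
        var_slow = config.rr_sd ** 2 * (
            c_q ** 2 + config.coupling_out ** 2 + config.individual_gain ** 2
        )
        beat_noise_sd = config.noise_frac * np.sqrt(var_slow)
        for pid in member_ids:
            own = _band_limited(config.individual_band, n_grid, rng)
            rr_inst = config.rr_mean + var_slow / config.rr_mean \
                + config.rr_sd * (
                    c_q * shared
                    + config.coupling_out * global_driver
                    + config.individual_gain * own
                )
            peaks = _r_peaks(rr_inst, -_PAD_S / 2, t_end + _PAD_S / 2,
                             beat_noise_sd, rng)
            participants.append(pid)
            quartet_of[pid] = qid
            segments[pid] = dict(windows)
            tachograms.append(Tachogram(participant=pid, r_peak_times=peaks))

        # ratings: quartet-level mean per (monologue, question), member
        # dispersion shrinking with agreement; identical at agreement = 1
        for mono in order:
            for question in RATING_QUESTIONS:
                mu = rng.uniform(2.0, 4.5)
                if agreement >= 1.0:
                    vals = np.full(4, mu)
                else:
                    sd = config.rating_sigma * (1.0 - agreement) + 0.05
                    vals = rng.normal(mu, sd, size=4)
                ratings = np.clip(np.rint(vals), 1, 5).astype(int)
                for pid, r in zip(member_ids, ratings):
                    rating_rows.append(
                        {"participant_id": pid, "monologue": mono,
                         "question": question, "rating": int(r)}
                    )

    manifest = SessionManifest(
        participants=sorted(participants),
        quartet_of=quartet_of,
        segments=segments,
        monologue_order=monologue_order,
    )
    manifest.validate()
    table = RatingTable(data=pd.DataFrame(rating_rows))
    table.validate()
    return manifest, tachograms, table


def simulate_fixture_small(
    seed: int,
) -> tuple[SessionManifest, list[Tachogram], RatingTable]:
    """Tiny deterministic fixture: 2 quartets, all segments exactly 2 min."""
    cfg = SimulationConfig(
        n_quartets=2,
        coupling_in=1.0,
        fixed_performance_s=240.0,
        rating_agreement=0.8,
        seed=seed,
    )
    return simulate_session(cfg)
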