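"""Synthetic cohorts with planted brain-state dynamics and behavior.

Each synthetic subject/condition is a T x V multichannel time series built
around a fixed baseline centroid: the pre-stimulus rows are the centroid plus
i.i.d. Gaussian noise; during the stimulus the state makes a piecewise-linear
excursion of controlled amplitude along a subject-specific random unit
direction — by default a trapezoid (steep ramps, flat engaged plateau) —
coming back to the baseline centroid exactly at the planted return time;
afterwards only a low-amplitude sinusoidal wobble remains. The steep final
ramp makes the planted return time an unambiguous ground truth for the
Mapper return-point marker.

Behavioral scores emulate the relations assumed by the downstream models:
accuracy declines linearly with both the planted return time and the median
reaction time, plus Gaussian noise, clipped to the percentage scale.

Everything is deterministic given a seed; per-subject streams are spawned
from a single numpy SeedSequence so cohorts are reproducible byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .mapper import StateSeries

__all__ = [
    "SynthParams",
    "BehavioralParams",
    "ReturnDistribution",
    "GroundTruth",
    "simulate_subject",
    "simulate_cohort",
    "BEHAVIORAL_COLUMNS",
]

#: behavioral-table schema (return-time columns are filled by the analysis)
BEHAVIORAL_COLUMNS = [
    "Subject",
    "0B Median Reaction",
    "2B Median Reaction",
    "0BAccuracy",
    "2BAccuracy",
]


@dataclass(frozen=True)
class SynthParams:
    """Geometry of one synthetic recording.

    ``excursion_amplitude`` is the peak displacement (in signal units) along
    the excursion direction; ``noise_sd`` the per-channel noise standard
    deviation; ``post_return_amplitude`` the amplitude of the residual wobble
    after the return. ``excursion_amplitude = 0`` plants a degenerate
    recording with no excursion (used to exercise the missing-return-point
    cleaning rules).

    The noise scale that competes with the excursion in state space is the
    noise's Euclidean magnitude noise_sd * sqrt(n_channels) (the distance
    noise floor), not the per-channel sd; only the ratio of amplitude to
    that floor fixes the geometry, independent of channel count. The default
    amplitude (``None``) is therefore derived as
    ``excursion_snr * noise_sd * sqrt(n_channels)``, so reducing the channel
    count for speed leaves the planted structure's geometry unchanged.
    """

    n_timepoints: int = 91
    n_channels: int = 642
    baseline_end: int = 30
    planted_return: int = 63
    excursion_amplitude: Optional[float] = None
    excursion_snr: float = 10.0
    noise_sd: float = 0.5
    post_return_amplitude: float = 0.5
    bump_shape: str = "plateau"  # "plateau" (trapezoid) or "triangle"
    ramp_samples: int = 4
    onset_delay: int = 2  # evoked-response latency: samples of near-zero toe
    onset_toe: float = 0.05  # bump level at the end of the latency segment
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bump_shape not in ("plateau", "triangle"):
            raise ValueError("bump_shape must be 'plateau' or 'triangle'")
        if self.ramp_samples < 1:
            raise ValueError("ramp_samples must be >= 1")
        if self.onset_delay < 0:
            raise ValueError("onset_delay must be >= 0")
        if not (0.0 < self.onset_toe < 1.0):
            raise ValueError("onset_toe must lie in (0, 1)")
        if not (self.baseline_end < self.planted_return <= self.n_timepoints):
            raise ValueError(
                "need baseline_end < planted_return <= n_timepoints, got "
                f"{self.baseline_end} / {self.planted_return} / {self.n_timepoints}"
            )
        if self.n_timepoints < self.baseline_end + 2:
            raise ValueError("too few time points for the baseline window")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.excursion_amplitude is None:
            object.__setattr__(
                self,
                "excursion_amplitude",
                self.excursion_snr * self.noise_sd * math.sqrt(self.n_channels),
            )
        if self.excursion_snr < 0:
            raise ValueError("excursion_snr must be >= 0")
        if self.excursion_amplitude < 0:
            raise ValueError("excursion_amplitude must be >= 0")
        if self.post_return_amplitude < 0:
            raise ValueError("post_return_amplitude must be >= 0")


@dataclass(frozen=True)
class BehavioralParams:
    """Linear coupling of accuracy to return time and reaction time.

    Accuracy (percent) = beta0 + beta_return * return + beta_rt * rt + noise,
    clipped to [0, 100]; reaction times (ms) are Gaussian, truncated positive.
    """

    beta0: float = 140.0
    beta_return: float = -0.5  # % per sample
    beta_rt: float = -0.02  # % per ms
    noise_sd_accuracy: float = 5.0
    rt_mean: float = 900.0
    rt_sd: float = 100.0

    def __post_init__(self) -> None:
        if self.noise_sd_accuracy < 0 or self.rt_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.rt_mean <= 0:
            raise ValueError("rt_mean must be positive")


@dataclass(frozen=True)
class ReturnDistribution:
    """Distribution of planted return times, on the 1-based sample scale.

    ``kind='normal'`` draws round(N(mean, sd)); ``kind='uniform'`` draws
    integers uniformly from [low, high]. Draws are clipped to the valid
    range (baseline_end + 2, n_timepoints].
    """

    kind: str = "normal"
    mean: float = 60.0
    sd: float = 2.0
    low: int = 50
    high: int = 80

    def sample(self, rng: np.random.Generator, params: SynthParams) -> int:
        if self.kind == "normal":
            draw = int(round(rng.normal(self.mean, self.sd)))
        elif self.kind == "uniform":
            draw = int(rng.integers(self.low, self.high + 1))
        else:
            raise ValueError(f"unknown return distribution kind {self.kind!r}")
        lo = params.baseline_end + 2
        hi = params.n_timepoints
        return int(np.clip(draw, lo, hi))


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for one generated recording."""

    subject: str
    condition: str
    planted_return: Optional[int]  # None for degenerate (no-excursion) series
    true_accuracy: Optional[float] = None
    true_reaction_time: Optional[float] = None


def _bump(
    t: np.ndarray,
    start: int,
    end: int,
    shape: str = "plateau",
    ramp: int = 4,
    delay: int = 2,
    toe: float = 0.05,
) -> np.ndarray:
    """Excursion profile on the window (start, end]: 0 at both anchors, peak 1.

    ``triangle`` rises linearly to 1 at the window midpoint and falls back.
    ``plateau`` (default) spends ``delay`` samples on a near-zero "toe"
    (reaching ``toe`` — the latency between stimulus onset and the evoked
    excursion, during which the state stays within the noise floor), ramps
    to 1 over ``ramp`` samples, holds flat, and falls back over the final
    ``ramp`` samples. The steep final ramp keeps the planted return sharp —
    the state re-enters the baseline vicinity only within a couple of
    samples of the nominal return — and the flat top reproduces the
    sustained mid-stimulus state behind the large engagement clusters.
    Windows too short for toe + both ramps degrade to the triangle.
    """
    t = np.asarray(t, dtype=float)
    if shape == "plateau" and end - start > delay + 2 * ramp:
        xs = [start, start + delay, start + delay + ramp, end - ramp, end]
        ys = [0.0, toe, 1.0, 1.0, 0.0]
        if delay == 0:
            xs, ys = xs[:1] + xs[2:], ys[:1] + ys[2:]
        return np.interp(t, xs, ys)
    mid = 0.5 * (start + end)
    up = (t - start) / (mid - start)
    down = (end - t) / (end - mid)
    return np.clip(np.minimum(up, down), 0.0, 1.0)


def simulate_subject(params: SynthParams) -> tuple[StateSeries, GroundTruth]:
    """Generate one recording with a planted excursion-and-return.

    Baseline rows are centroid + noise; stimulus rows up to the planted
    return add a piecewise-linear excursion along a fixed random unit
    direction (zero again exactly at the planted return); later rows add
    only a bounded sinusoidal wobble of amplitude ``post_return_amplitude``.
    """
    rng = np.random.default_rng(params.seed)
    t_n, v = params.n_timepoints, params.n_channels
    mu0 = rng.normal(0.0, 1.0, size=v)
    u = rng.normal(size=v)
    u /= np.linalg.norm(u)

    times = np.arange(1, t_n + 1)
    signal = np.zeros(t_n)
    degenerate = params.excursion_amplitude == 0.0
    if not degenerate:
        exc = (times > params.baseline_end) & (times <= params.planted_return)
        signal[exc] = params.excursion_amplitude * _bump(
            times[exc].astype(float),
            params.baseline_end,
            params.planted_return,
            params.bump_shape,
            params.ramp_samples,
            params.onset_delay,
            params.onset_toe,
        )
        post = times > params.planted_return
        # period chosen shorter than typical post-return windows so the
        # wobble is visibly oscillatory, never a second excursion
        signal[post] = params.post_return_amplitude * np.sin(
            2.0 * math.pi * (times[post] - params.planted_return) / 16.0
        )

    noise = rng.normal(0.0, params.noise_sd, size=(t_n, v)) if params.noise_sd > 0 else 0.0
    values = mu0[None, :] + signal[:, None] * u[None, :] + noise
    series = StateSeries(
        values, baseline_end=params.baseline_end, subject=f"S{params.seed:04d}"
    )
    truth = GroundTruth(
        subject=series.subject,
        condition=series.condition,
        planted_return=None if degenerate else params.planted_return,
    )
    return series, truth


def simulate_cohort(
    n_subjects: int = 70,
    return_dist_0B: ReturnDistribution = ReturnDistribution("normal", 60.0, 2.0),
    return_dist_2B: ReturnDistribution = ReturnDistribution("normal", 68.0, 2.0),
    synth: SynthParams = SynthParams(),
    behav: BehavioralParams = BehavioralParams(),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], StateSeries], pd.DataFrame, pd.DataFrame]:
    """Generate a two-condition cohort with planted returns and behavior.

    Each subject gets one recording per condition (0B, 2B) with the planted
    return drawn from the matching distribution. A ``missing_rate`` fraction
    of subjects receive a degenerate no-excursion recording in one randomly
    chosen condition, to exercise the missing-return-point cleaning rules.

    Returns ``(series, behavioral, ground_truth)``: a dict keyed by
    (subject, condition), the behavioral table (BEHAVIORAL_COLUMNS schema),
    and the ground-truth table (one row per recording).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not (0.0 <= missing_rate <= 1.0):
        raise ValueError("missing_rate must be in [0, 1]")

    master = np.random.SeedSequence(seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    subject_seeds = master.generate_state(2 * n_subjects) % (2**31)

    series: dict[tuple[str, str], StateSeries] = {}
    truth_rows = []
    behav_rows = []
    dists = {"0B": return_dist_0B, "2B": return_dist_2B}
    for i in range(n_subjects):
        subject = f"S{i:04d}"
        degenerate_cond = None
        if missing_rate > 0 and rng.random() < missing_rate:
            degenerate_cond = "0B" if rng.random() < 0.5 else "2B"
        row: dict[str, object] = {"Subject": subject}
        for j, cond in enumerate(("0B", "2B")):
            planted = dists[cond].sample(rng, synth)
            amplitude = 0.0 if cond == degenerate_cond else synth.excursion_amplitude
            p = replace(
                synth,
                planted_return=planted,
                excursion_amplitude=amplitude,
                seed=int(subject_seeds[2 * i + j]),
            )
            s, _ = simulate_subject(p)
            s = StateSeries(s.values, s.baseline_end, subject=subject, condition=cond)
            series[(subject, cond)] = s

            rt = max(1.0, rng.normal(behav.rt_mean, behav.rt_sd))
            true_acc = behav.beta0 + behav.beta_return * planted + behav.beta_rt * rt
            acc = float(
                np.clip(true_acc + rng.normal(0.0, behav.noise_sd_accuracy), 0.0, 100.0)
            )
            truth_rows.append(
                GroundTruth(
                    subject, cond,
                    None if amplitude == 0.0 else planted,
                    true_accuracy=true_acc,
                    true_reaction_time=rt,
                )
            )
            row[f"{cond} Median Reaction"] = rt
            row[f"{cond}Accuracy"] = acc
        behav_rows.append(row)

    behavioral = pd.DataFrame(behav_rows, columns=BEHAVIORAL_COLUMNS)
    ground_truth = pd.DataFrame(
        [
            {
                "Subject": g.subject,
                "Condition": g.condition,
                "PlantedReturn": g.planted_return,
                "TrueAccuracy": g.true_accuracy,
                "TrueReactionTime": g.true_reaction_time,
            }
            for g in truth_rows
        ]
    )
    return series, behavioral, ground_truth
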