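"""Synthetic paired cohorts of 10 Hz tri-axial accelerometer recordings.

The generator emulates the structure of a school-day wrist/ankle recording:

* a gravity vector of magnitude 1 g whose direction drifts slowly (posture
  changes and sensor-strap creep), realised as a small-step random walk on
  the unit sphere;
* sporadic movement bursts — exponentially damped sinusoids with a random 3-D
  direction — arriving as a Poisson process, with group-dependent rate and
  peak-amplitude distributions;
* additive white Gaussian sensor noise.

The group contrast is purely kinematic: ADHD-like participants produce more
frequent and more intense bursts (log-normal peak amplitudes centred in the
high-intensity region around 1.3–2.8 g reported for ADHD movement, versus
below 0.8 g for controls), while gravity drift and noise are identical across
groups.  A scalar ``effect_size`` in [0, 1] interpolates the ADHD generative
parameters between the control values (0 → groups indistinguishable) and the
full contrast (1).  Medicated-group parameters sit between the two, pulled
toward control by ``medicated_shift``.

Seeding is hierarchical (master seed → participant → bursts via numpy
``SeedSequence.spawn``), so enlarging a cohort never perturbs existing
participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_core import AccelSeries

__all__ = [
    "SimConfig",
    "SimParticipant",
    "SimCohort",
    "group_params",
    "simulate_participant",
    "simulate_cohort",
]


@dataclass
class SimConfig:
    """Generative parameters of the synthetic cohort.

    Amplitudes are in g, rates per minute, durations in seconds.  The control
    peak-amplitude distribution is log-normal with median
    ``control_burst_peak_g`` (mass concentrated below 0.8 g); the ADHD-like
    distribution at full effect has median ``adhd_burst_peak_g`` (mass in the
    1.3–2.8 g region).
    """

    n_pairs: int = 8
    n_medicated: int = 0
    session_hours: float = 0.5
    sample_rate_hz: float = 10.0
    sites: tuple[str, ...] = ("wrist", "ankle")
    gravity_drift_rad_s: float = 0.02
    control_burst_rate_per_min: float = 6.0
    adhd_burst_rate_per_min: float = 12.0
    control_burst_peak_g: float = 0.45
    adhd_burst_peak_g: float = 1.8
    burst_peak_log_sd: float = 0.35
    burst_freq_hz: tuple[float, float] = (1.0, 4.0)
    burst_decay_s: tuple[float, float] = (0.2, 0.6)
    noise_sd_g: float = 0.02
    effect_size: float = 1.0
    medicated_shift: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")
        if not 0.0 <= self.medicated_shift <= 1.0:
            raise ValueError("medicated_shift must lie in [0, 1]")
        for name in ("n_pairs", "session_hours", "sample_rate_hz",
                     "control_burst_rate_per_min", "adhd_burst_rate_per_min",
                     "control_burst_peak_g", "adhd_burst_peak_g", "noise_sd_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SimParticipant:
    participant_id: str
    group: str
    pair_id: str
    snap_score: float
    series: dict[str, AccelSeries] = field(default_factory=dict)


@dataclass
class SimCohort:
    participants: list[SimParticipant]
    config: SimConfig

    def manifest(self):
        import pandas as pd

        return pd.DataFrame(
            [{"participant_id": p.participant_id, "group": p.group,
              "pair_id": p.pair_id, "snap_score": p.snap_score}
             for p in self.participants]
        )


def group_params(group: str, config: SimConfig) -> tuple[float, float]:
    """Burst rate (per min) and log-normal peak median (g) for one group.

    The ADHD contrast is scaled by ``effect_size`` (linearly for the rate,
    geometrically for the amplitude median); the medicated group sits
    ``medicated_shift`` of the way back toward control.
    """
    e = config.effect_size
    if group == "control":
        e = 0.0
    elif group == "adhd_med":
        e = e * (1.0 - config.medicated_shift)
    elif group != "adhd_nonmed":
        raise ValueError(f"unknown group {group!r}")
    rate = config.control_burst_rate_per_min + e * (
        config.adhd_burst_rate_per_min - config.control_burst_rate_per_min
    )
    log_peak = (1 - e) * np.log(config.control_burst_peak_g) + e * np.log(
        config.adhd_burst_peak_g
    )
    return rate, float(np.exp(log_peak))


def _gravity_walk(n: int, dt: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Slowly drifting unit gravity direction: random walk projected to the sphere."""
    v0 = rng.normal(size=3)
    v0 /= np.linalg.norm(v0)
    steps = rng.normal(0.0, rate * dt, size=(n, 3))
    walk = v0 + np.cumsum(steps, axis=0)
    walk[0] = v0
    return walk / np.linalg.norm(walk, axis=1, keepdims=True)


def sample_burst(rng: np.random.Generator, config: SimConfig,
                 peak_median: float) -> tuple[float, float, float, np.ndarray]:
    """Draw one movement burst: (peak amplitude g, frequency Hz, decay s, direction).

    The peak is log-normal around ``peak_median``; frequency and decay are
    uniform over their configured ranges; the direction is uniform on the
    sphere.  This is the exact code path :func:`simulate_participant` uses,
    so Monte-Carlo calibration checks exercise the generator itself.
    """
    peak = peak_median * np.exp(rng.normal(0.0, config.burst_peak_log_sd))
    freq = rng.uniform(*config.burst_freq_hz)
    tau = rng.uniform(*config.burst_decay_s)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    return peak, freq, tau, direction


def _burst_waveform(t_rel: np.ndarray, peak: float, freq: float, tau: float) -> np.ndarray:
    """Exponentially damped sinusoid, normalised so its peak magnitude is ``peak``."""
    raw = np.exp(-t_rel / tau) * np.sin(2 * np.pi * freq * t_rel)
    top = np.max(np.abs(raw))
    if top == 0:
        return raw
    return peak * raw / top


def simulate_participant(group: str, config: SimConfig, seed, site: str = "wrist",
                         participant_id: str = "sim") -> AccelSeries:
    """Simulate one sensor recording for one participant.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.  The output is
    gravity drift + movement bursts + noise; at rest ``|a| ≈ 1`` g.
    """
    rng = np.random.default_rng(seed)
    fs = config.sample_rate_hz
    dt = 1.0 / fs
    n = int(round(config.session_hours * 3600 * fs))
    t = np.arange(n) * dt

    g = _gravity_walk(n, dt, config.gravity_drift_rad_s, rng)
    a_m = np.zeros((n, 3))

    rate_per_min, peak_median = group_params(group, config)
    n_bursts = rng.poisson(rate_per_min * config.session_hours * 60.0)
    starts = np.sort(rng.uniform(0.0, t[-1] if n > 1 else 0.0, size=n_bursts))
    for t0 in starts:
        peak, freq, tau, direction = sample_burst(rng, config, peak_median)
        dur = 3.0 * tau
        i0 = int(np.ceil(t0 * fs))
        i1 = min(n, int(np.floor((t0 + dur) * fs)) + 1)
        if i0 >= i1:
            continue
        wave = _burst_waveform(t[i0:i1] - t0, peak, freq, tau)
        a_m[i0:i1] += wave[:, None] * direction

    a = g + a_m + rng.normal(0.0, config.noise_sd_g, size=(n, 3))
    return AccelSeries(
        participant_id=participant_id,
        sensor_site=site,
        sample_rate_hz=fs,
        t=t,
        a=a,
    )


def simulate_cohort(config: SimConfig | None = None) -> SimCohort:
    """Simulate a paired cohort with per-participant derived seeds.

    ``n_pairs`` (ADHD non-medicated, control) pairs plus ``n_medicated``
    unpaired-by-default medicated participants (each medicated child is
    paired with an extra control to keep the cohort pairing a bijection).
    Synthetic SNAP scores are drawn above the 1.44 diagnostic cut for ADHD
    members and below it for controls.
    """
    config = config or SimConfig()
    n_extra = config.n_medicated
    roster: list[tuple[str, str, str]] = []       # (id, group, pair_id)
    for k in range(config.n_pairs):
        roster.append((f"adhd{k + 1:02d}", "adhd_nonmed", f"pair{k + 1:02d}"))
        roster.append((f"control{k + 1:02d}", "control", f"pair{k + 1:02d}"))
    for k in range(n_extra):
        j = config.n_pairs + k + 1
        roster.append((f"adhd{j:02d}m", "adhd_med", f"pair{j:02d}"))
        roster.append((f"control{j:02d}", "control", f"pair{j:02d}"))

    master = np.random.SeedSequence(config.seed)
    child_seqs = master.spawn(len(roster))
    participants = []
    for (pid, group, pair_id), seq in zip(roster, child_seqs):
        site_seqs = seq.spawn(len(config.sites) + 1)
        snap_rng = np.random.default_rng(site_seqs[-1])
        snap = (round(float(snap_rng.uniform(1.5, 3.0)), 2) if group != "control"
                else round(float(snap_rng.uniform(0.0, 1.0)), 2))
        series = {
            site: simulate_participant(group, config, site_seq, site=site,
                                       participant_id=pid)
            for site, site_seq in zip(config.sites, site_seqs)
        }
        participants.append(SimParticipant(
            participant_id=pid, group=group, pair_id=pair_id,
            snap_score=snap, series=series,
        ))
    return SimCohort(participants=participants, config=config)
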