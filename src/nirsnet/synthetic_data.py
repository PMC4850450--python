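"""Synthetic multichannel fNIRS-like recordings with a controllable group
structure.

The study these tools emulate recorded 24-channel prefrontal HbO2 time series
(10 Hz, mM·mm) from two behavioral conditions — spontaneous versus instructed
("control") deception — with six trial types (win-win / lose-win / lose-lose
crossed with the two conditions).  No public data accompany the study, so this
module generates recordings whose inter-channel correlation structure can be
dialed per group: every downstream stage (filtering, epoching, network
construction, threshold sweep, group statistics) is testable end to end
without any download.

Generative model per channel c in latent community m(c) and sub-cluster
s(c)::

    x_c(t) = a_s * [lat_{m(c)}(t) + d * sub_{s(c)}(t)]
             + evoked(t) + phys(t) + w * v_c * eps_c(t)

* ``lat_m`` — community latent signal, white Gaussian, unit SD, mixed with the
  other communities through ``cross_community_mix`` so that between-community
  correlations are nonzero but weaker than within-community ones.
* ``sub_s`` — an extra latent shared by a small block of channels (default 4,
  weight ``d = subcluster_scale``), modelling tight local optode patches;
  these blocks are what give the thresholded networks their above-random
  clustering.
* ``a_s`` — group coupling (``group_coupling``), jittered per subject.
* ``evoked`` — hemodynamic response (double-gamma kernel) convolved with the
  trial onset train; identical across channels (a global evoked component).
* ``phys`` — sinusoidal physiological oscillations (Mayer ~0.1 Hz, respiratory
  ~0.3 Hz, cardiac ~1.1 Hz), shared across channels: these are systemic.
* ``eps_c`` — independent white Gaussian channel noise; ``v_c`` draws a
  per-channel (log-uniform) noise scale so that pairwise correlations form a
  graded distribution rather than a single value, which is what makes a
  threshold sweep informative.

Latent and channel noise share the same (flat) spectrum, so the band-pass
filter applied during preprocessing attenuates both equally and the designed
correlation contrast survives filtering.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gamma as _gamma

__all__ = [
    "CASES",
    "GROUPS",
    "SimulationConfig",
    "Recording",
    "canonical_hrf",
    "simulate_recording",
    "simulate_cohort",
]

#: Trial types (outcome-answer pairs of the card game).
CASES = ("win-win", "lose-win", "lose-lose")

#: Behavioral conditions: freely chosen versus instructed answers.
GROUPS = ("spontaneous", "control")

# Within-community population correlations span roughly the sweep grid
# [0.275, 0.625] for both groups, with the spontaneous group shifted upward.
DEFAULT_GROUP_COUPLING: Mapping[str, float] = {"spontaneous": 0.92, "control": 0.60}

#: (frequency Hz, amplitude) systemic oscillators.  The cardiac band sits above
#: the 0.3 Hz analysis low-pass and is removed during preprocessing.
DEFAULT_NOISE_BANDS = ((0.1, 0.05), (0.3, 0.05), (1.1, 0.25))


def default_partition(n_channels: int) -> tuple[int, ...]:
    """Two equal communities, mimicking bilateral frontal optode patches."""
    half = n_channels // 2
    return tuple([0] * half + [1] * (n_channels - half))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study: 24 subjects, 24 channels, 10 Hz
    sampling, 13-s epochs (2 s pre-stimulus + 11 s post), 10 trials per case.
    """

    n_subjects: int = 24
    n_channels: int = 24
    fs: float = 10.0
    n_trials_per_case: int = 10
    epoch_pre_s: float = 2.0
    epoch_post_s: float = 11.0
    group_coupling: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_COUPLING)
    )
    community_partition: tuple[int, ...] | None = None
    noise_bands: tuple[tuple[float, float], ...] = DEFAULT_NOISE_BANDS
    white_noise_sd: float = 0.6
    #: log-uniform range of the per-channel noise-scale multiplier v_c
    channel_noise_range: tuple[float, float] = (0.35, 2.0)
    #: mixing weight of the other communities' latents into a channel's latent
    cross_community_mix: float = 0.5
    #: channels per tight sub-cluster within a community (None: no sub-clusters);
    #: sub-clusters model small optode patches with extra local coherence and
    #: give the networks their above-random clustering
    subcluster_size: int | None = 4
    #: weight of the sub-cluster latent relative to the group coupling
    subcluster_scale: float = 0.75
    evoked_amplitude: float = 0.08
    #: multiplicative subject-level jitter applied to the group coupling
    subject_coupling_jitter: float = 0.05
    lead_in_s: float = 5.0
    inter_trial_gap_s: float = 2.0
    seed: int = 0

    @property
    def partition(self) -> tuple[int, ...]:
        if self.community_partition is not None:
            return tuple(self.community_partition)
        return default_partition(self.n_channels)

    @property
    def epoch_samples(self) -> int:
        return int(round((self.epoch_pre_s + self.epoch_post_s) * self.fs))

    def validate(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_trials_per_case < 1:
            raise ValueError("n_trials_per_case must be >= 1")
        total = (self.epoch_pre_s + self.epoch_post_s) * self.fs
        if abs(total - round(total)) > 1e-9:
            raise ValueError("epoch length times fs must be an integer sample count")
        for g, a in self.group_coupling.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"coupling for {g!r} must lie in [0, 1]")
        if len(self.partition) != self.n_channels:
            raise ValueError("community_partition must assign every channel")
        if not 0.0 <= self.cross_community_mix < 1.0:
            raise ValueError("cross_community_mix must lie in [0, 1)")
        if self.white_noise_sd < 0:
            raise ValueError("white_noise_sd must be >= 0")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")


@dataclass
class Recording:
    """One subject's multichannel HbO2 time series with trial markers.

    ``data`` has one row per channel (units: mM·mm change from baseline);
    ``markers`` holds (onset sample, case label) pairs, onsets aligned to
    stimulus delivery.
    """

    subject_id: str
    group: str
    channels: list[str]
    data: np.ndarray
    fs: float
    markers: list[tuple[int, str]]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def validate(
        self, epoch_pre_s: float = 2.0, epoch_post_s: float = 11.0
    ) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must have one row per channel")
        pre = int(round(epoch_pre_s * self.fs))
        post = int(round(epoch_post_s * self.fs))
        for onset, case in self.markers:
            if case not in CASES:
                raise ValueError(f"unknown case label {case!r}")
            if onset - pre < 0 or onset + post > self.n_samples:
                raise ValueError(
                    f"marker at sample {onset} does not allow a full "
                    f"{epoch_pre_s}s-pre/{epoch_post_s}s-post window"
                )


def canonical_hrf(fs: float, duration_s: float) -> np.ndarray:
    """Double-gamma hemodynamic response kernel, peak-normalized to 1.

    Response gamma(shape=6) peaks at 5 s; undershoot gamma(shape=16)/6 dips
    around 15 s.  The kernel is 0 at t = 0 and its maximum falls on the sample
    grid for any fs whose grid contains t = 5 s.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * fs))
    if n < 1:
        raise ValueError("duration too short for one sample")
    t = np.arange(n) / fs
    h = _gamma.pdf(t, 6.0) - _gamma.pdf(t, 16.0) / 6.0
    return h / h.max()


def _subject_seed_sequence(
    config: SimulationConfig, subject_id: str, group: str
) -> np.random.SeedSequence:
    """Master-seed -> per-subject seed: crc32 of "subject|group" mixed with the
    master seed through SeedSequence.  Subjects (and the two group-level
    recordings of a subject id) are therefore independent but reproducible."""
    key = zlib.crc32(f"{subject_id}|{group}".encode())
    return np.random.SeedSequence([int(config.seed), key])


def _trial_schedule(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Onset samples and case indices for the randomized trial order."""
    n_trials = config.n_trials_per_case * len(CASES)
    case_idx = rng.permutation(np.repeat(np.arange(len(CASES)), config.n_trials_per_case))
    slot = config.epoch_samples + int(round(config.inter_trial_gap_s * config.fs))
    lead = int(round(config.lead_in_s * config.fs))
    pre = int(round(config.epoch_pre_s * config.fs))
    onsets = lead + slot * np.arange(n_trials) + pre
    return onsets, case_idx


def simulate_recording(
    config: SimulationConfig, subject_id: str, group: str
) -> Recording:
    """Generate one subject's recording for one behavioral group.

    Deterministic given (config.seed, subject_id, group).  The fixed draw
    order is: trial schedule, per-trial evoked amplitudes, oscillator phases,
    community latents, channel noise scales, channel noise, coupling jitter.
    """
    config.validate()
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}; expected one of {GROUPS}")

    rng = np.random.default_rng(_subject_seed_sequence(config, subject_id, group))
    onsets, case_idx = _trial_schedule(config, rng)
    slot = config.epoch_samples + int(round(config.inter_trial_gap_s * config.fs))
    lead = int(round(config.lead_in_s * config.fs))
    n = lead + slot * len(onsets)

    # shared evoked component: HRF-convolved onset train, jittered amplitudes
    amps = config.evoked_amplitude * rng.uniform(0.8, 1.2, size=len(onsets))
    stick = np.zeros(n)
    stick[onsets] = amps
    hrf = canonical_hrf(config.fs, config.epoch_pre_s + config.epoch_post_s)
    evoked = np.convolve(stick, hrf)[:n]

    # shared systemic oscillations
    t = np.arange(n) / config.fs
    phys = np.zeros(n)
    for freq, amp in config.noise_bands:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        phys += amp * np.sin(2.0 * np.pi * freq * t + phase)

    partition = np.asarray(config.partition)
    communities = np.unique(partition)
    latents = rng.standard_normal((len(communities), n))

    # tight sub-clusters: consecutive channels within a community share an
    # extra local latent, the source of above-random clustering
    if config.subcluster_size:
        sub_of = np.empty(config.n_channels, dtype=int)
        next_id = 0
        for comm in communities:
            members = np.flatnonzero(partition == comm)
            for start in range(0, len(members), config.subcluster_size):
                sub_of[members[start : start + config.subcluster_size]] = next_id
                next_id += 1
        sub_latents = rng.standard_normal((next_id, n))
    else:
        sub_of = None
        sub_latents = None

    lo, hi = config.channel_noise_range
    v = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_channels))
    eps = rng.standard_normal((config.n_channels, n))

    coupling = float(config.group_coupling[group])
    jitter = config.subject_coupling_jitter
    a = float(np.clip(coupling * (1.0 + jitter * rng.uniform(-1.0, 1.0)), 0.0, 1.0))

    gamma = config.cross_community_mix
    own_w = np.sqrt(1.0 - gamma**2)
    data = np.empty((config.n_channels, n))
    for c in range(config.n_channels):
        m = int(np.searchsorted(communities, partition[c]))
        lat = latents[m]
        if len(communities) > 1 and gamma > 0:
            others = np.delete(np.arange(len(communities)), m)
            cross = latents[others].sum(axis=0) / np.sqrt(len(others))
            lat = own_w * lat + gamma * cross
        if sub_latents is not None:
            lat = lat + config.subcluster_scale * sub_latents[sub_of[c]]
        data[c] = a * lat + evoked + phys + config.white_noise_sd * v[c] * eps[c]

    channels = [f"CH{i + 1:02d}" for i in range(config.n_channels)]
    markers = [(int(o), CASES[i]) for o, i in zip(onsets, case_idx)]
    rec = Recording(
        subject_id=str(subject_id),
        group=group,
        channels=channels,
        data=data,
        fs=config.fs,
        markers=markers,
    )
    rec.validate(config.epoch_pre_s, config.epoch_post_s)
    return rec


def simulate_cohort(config: SimulationConfig) -> list[Recording]:
    """One recording per subject per group (2 × n_subjects recordings).

    The study recorded the same subjects in both behavioral conditions; the
    generator draws the two conditions independently, matching the unpaired
    two-sample comparison used downstream.
    """
    config.validate()
    recordings = []
    for group in GROUPS:
        for i in range(config.n_subjects):
            subject_id = f"S{i + 1:02d}"
            recordings.append(simulate_recording(config, subject_id, group))
    return recordings
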