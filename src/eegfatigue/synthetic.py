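"""Synthetic cohorts of EEG-like recordings plus subjective fatigue scores.

Each channel is a weighted sum of band-limited oscillations (one per
analysis band) over a pink (1/f) plus white noise floor.  During the
physical task event (s2) the theta/alpha weights increase and a
complexity-reducing moving-average blend is applied, both in proportion
to the subject's physical fatigue gain times the session intensity;
during the mental task event (s3) likewise with the mental gain.  The
per-channel strength of this fatigue signature is set by the profile's
``channel_gains`` (0 = the channel carries no signature).

Subjective scores increase with the same gains, so threshold labelling
downstream is consistent with the injected signal shifts.

Everything is a pure function of (inputs, seed); per-subject seeds are
derived from the master seed via ``SeedSequence([master_seed, index])``
(see :mod:`eegfatigue._seeds`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from eegfatigue._seeds import rng_for
from eegfatigue.constants import BANDS, CHANNELS, EVENTS, SAMPLING_RATE
from eegfatigue.errors import ConfigurationError, ScheduleError
from eegfatigue.segmentation import EventSchedule, Recording, write_recording_csv

logger = logging.getLogger(__name__)

INTENSITIES = ("low", "medium", "high")
INTENSITY_FACTOR = {"low": 1.0 / 3.0, "medium": 2.0 / 3.0, "high": 1.0}

#: Typical resting band weights used as the profile baseline.
DEFAULT_BAND_WEIGHTS = {"delta": 0.40, "theta": 0.25, "alpha": 0.20, "beta": 0.15}

_BAND_EDGES = {name: (lo, hi) for name, lo, hi in BANDS}


@dataclass
class SubjectProfile:
    """Per-subject generation parameters."""

    subject_id: str
    baseline_band_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_WEIGHTS)
    )
    fatigue_gain_physical: float = 1.0
    fatigue_gain_mental: float = 1.0
    noise_scale: float = 0.3
    channel_gains: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in CHANNELS}
    )
    #: Optional separate per-channel gains for the mental (s3) signature;
    #: ``None`` applies ``channel_gains`` to both task events.  Distinct
    #: maps let two channels carry complementary signatures.
    channel_gains_mental: dict[str, float] | None = None
    #: Baseline subjective score on the configured instrument scale.
    baseline_score: float = 20.0

    def __post_init__(self) -> None:
        for gains in (self.channel_gains, self.channel_gains_mental):
            if gains is None:
                continue
            if set(gains) != set(CHANNELS):
                raise ConfigurationError(
                    f"channel gains must cover exactly {CHANNELS}, got {tuple(gains)}"
                )
            if any(g < 0 or not np.isfinite(g) for g in gains.values()):
                raise ConfigurationError("channel gains must be finite and >= 0")
        weights = self.baseline_band_weights
        if set(weights) != set(_BAND_EDGES):
            raise ConfigurationError(
                f"band weights must cover exactly {tuple(_BAND_EDGES)}"
            )
        total = sum(weights.values())
        if not np.isfinite(total) or total <= 0 or any(w < 0 for w in weights.values()):
            raise ConfigurationError("band weights must be nonnegative with positive sum")
        for name in ("fatigue_gain_physical", "fatigue_gain_mental"):
            v = getattr(self, name)
            if v < 0 or not np.isfinite(v):
                raise ConfigurationError(f"{name} must be finite and >= 0")
        if self.noise_scale <= 0 and self.noise_scale != 0.0:
            raise ConfigurationError("noise_scale must be >= 0")


@dataclass(frozen=True)
class SessionPlan:
    """One session: intensity plus the event schedule."""

    session_index: int
    intensity: str
    s3_duration_s: int = 540
    sampling_rate: int = SAMPLING_RATE
    #: Optional desk-scale override of every event duration (seconds).
    #: ``None`` uses the standard fixed durations.
    event_durations: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.intensity not in INTENSITIES:
            raise ScheduleError(f"intensity must be one of {INTENSITIES}")
        if not 1 <= self.session_index <= 3:
            raise ScheduleError("session_index must be in 1..3")
        if self.sampling_rate <= 0:
            raise ScheduleError("sampling rate must be positive")
        if self.s3_duration_s < 0 or self.s3_duration_s > 900:
            raise ScheduleError("s3 duration must be in [0, 900] s")

    @property
    def schedule(self) -> EventSchedule:
        if self.event_durations is not None:
            durations = {e: int(self.event_durations[e]) for e in EVENTS}
        else:
            durations = {"s1": 180, "m1": 120, "s2": 180, "m2": 120,
                         "s3": self.s3_duration_s, "m3": 120}
        return EventSchedule(durations=durations, sampling_rate=self.sampling_rate)

    @property
    def total_duration_s(self) -> int:
        total = self.schedule.total_s
        assert total is not None
        return total


@dataclass
class FatigueScores:
    """Subjective scores for one subject-session (one per task event)."""

    subject_id: str
    session_index: int
    baseline_score: float
    physical_score: float
    mental_score: float

    def to_rows(self) -> list[dict]:
        return [
            {"subject": self.subject_id, "session": self.session_index,
             "event": event, "score": score}
            for event, score in (
                ("s1", self.baseline_score),
                ("s2", self.physical_score),
                ("s3", self.mental_score),
            )
        ]


def default_plans(
    s3_duration_s: int = 540, event_durations: dict[str, int] | None = None
) -> list[SessionPlan]:
    """Three sessions at increasing physical intensity."""
    return [
        SessionPlan(i + 1, intensity, s3_duration_s=s3_duration_s,
                    event_durations=event_durations)
        for i, intensity in enumerate(INTENSITIES)
    ]


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping, unit SD."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0
    pink = np.fft.irfft(spectrum * scale, n=n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


@lru_cache(maxsize=None)
def _band_sos(lo: float, hi: float, fs: int):
    return butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _band_component(
    band: str, n: int, fs: int, rng: np.random.Generator, mode: str
) -> np.ndarray:
    """Unit-SD band-limited oscillation.

    ``narrowband`` filters white noise into the band (order-4 Butterworth,
    zero-phase).  ``tone`` is a sinusoid at the band centre frequency with
    a random phase (the alpha centre is exactly 10 Hz).
    """
    lo, hi = _BAND_EDGES[band]
    if mode == "tone":
        f0 = 0.5 * (lo + hi)
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * f0 * t + phase)
        return x * np.sqrt(2.0)  # unit SD
    if mode != "narrowband":
        raise ConfigurationError(f"unknown oscillation mode {mode!r}")
    x = sosfiltfilt(_band_sos(lo, hi, fs), rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def _event_effect(event: str, profile: SubjectProfile, plan: SessionPlan) -> float:
    if event == "s2":
        return profile.fatigue_gain_physical * INTENSITY_FACTOR[plan.intensity]
    if event == "s3":
        return profile.fatigue_gain_mental
    return 0.0


#: Strength of the theta/alpha weight boost per unit effect.
_BOOST = 1.0
#: Strength of the moving-average blend per unit effect (complexity drop).
_SMOOTH = 0.5
_SMOOTH_WIDTH = 9


def generate_recording(
    profile: SubjectProfile,
    plan: SessionPlan,
    seed: int,
    oscillation_mode: str = "narrowband",
) -> Recording:
    """Synthesise one subject-session recording.

    Deterministic per (profile, plan, seed): each (channel, event) block
    draws from its own seed-derived stream, so outputs do not depend on
    iteration order.
    """
    fs = plan.sampling_rate
    schedule = plan.schedule
    events = [(e, schedule.durations[e]) for e in EVENTS]
    channels: dict[str, np.ndarray] = {}
    mental_gains = profile.channel_gains_mental or profile.channel_gains
    for ch_idx, channel in enumerate(CHANNELS):
        pieces = []
        for ev_idx, (event, duration) in enumerate(events):
            n = duration * fs
            if n == 0:
                continue
            rng = rng_for(seed, ch_idx, ev_idx)
            gains = mental_gains if event == "s3" else profile.channel_gains
            effect = _event_effect(event, profile, plan) * gains[channel]
            signal = np.zeros(n)
            for band, base_weight in profile.baseline_band_weights.items():
                weight = base_weight
                if band in ("theta", "alpha"):
                    weight *= 1.0 + _BOOST * effect
                if weight > 0:
                    signal += weight * _band_component(band, n, fs, rng, oscillation_mode)
            if profile.noise_scale > 0:
                signal += profile.noise_scale * (
                    0.7 * _pink_noise(n, rng) + 0.3 * rng.standard_normal(n)
                )
            lam = min(0.9, _SMOOTH * effect)
            if lam > 0:
                signal = (1.0 - lam) * signal + lam * _moving_average(signal, _SMOOTH_WIDTH)
            pieces.append(signal)
        channels[channel] = np.concatenate(pieces) if pieces else np.zeros(0)
    return Recording(
        subject_id=profile.subject_id,
        session_index=plan.session_index,
        channels=channels,
        sampling_rate=fs,
    )


# ---------------------------------------------------------------------------
# Subjective scores
# ---------------------------------------------------------------------------

#: Instrument-scale slopes: score points added per unit (gain x intensity).
PHYSICAL_SLOPE = 30.0
MENTAL_SLOPE = 25.0
#: Score noise SD per unit profile noise_scale.
SCORE_NOISE_SD = 10.0


def generate_scores(
    profile: SubjectProfile, plan: SessionPlan, seed: int
) -> FatigueScores:
    """Subjective scores for one subject-session (deterministic per seed)."""
    rng = rng_for(seed, "scores")
    noise_sd = profile.noise_scale * SCORE_NOISE_SD

    def draw(base: float) -> float:
        return max(0.0, base + noise_sd * rng.standard_normal())

    baseline = draw(profile.baseline_score)
    physical = draw(
        profile.baseline_score
        + PHYSICAL_SLOPE * profile.fatigue_gain_physical * INTENSITY_FACTOR[plan.intensity]
    )
    mental = draw(profile.baseline_score + MENTAL_SLOPE * profile.fatigue_gain_mental)
    return FatigueScores(
        subject_id=profile.subject_id,
        session_index=plan.session_index,
        baseline_score=baseline,
        physical_score=physical,
        mental_score=mental,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """All recordings and scores of a generated cohort."""

    profiles: list[SubjectProfile]
    plans: list[SessionPlan]
    recordings: dict[tuple[str, int], Recording]
    scores: pd.DataFrame
    manifest: dict

    def iter_recordings(self):
        """Yield (recording, schedule) pairs for feature extraction."""
        plan_by_session = {p.session_index: p for p in self.plans}
        for (_, session), rec in self.recordings.items():
            yield rec, plan_by_session[session].schedule


def make_profile(
    subject_index: int,
    master_seed: int,
    informative_channels=CHANNELS,
    uninformative_gain: float = 0.1,
    gain_physical_range: tuple[float, float] = (0.8, 1.6),
    gain_mental_range: tuple[float, float] = (0.8, 1.6),
    noise_scale: float = 0.3,
    baseline_score: float = 20.0,
    complementary: bool = False,
    gain_bimodal: bool = False,
) -> SubjectProfile:
    """Draw one subject's profile from the cohort's parameter ranges.

    With ``complementary`` and two or more informative channels, the first
    half of ``informative_channels`` carries the physical (s2) signature
    and the second half the mental (s3) signature, so no single channel
    sees both.

    With ``gain_bimodal`` the cohort splits into fatigue-prone and
    fatigue-resistant phenotypes (alternating by subject index): gains are
    drawn from the top or bottom 15% of the configured range instead of
    uniformly, which removes borderline subjects.
    """
    rng = rng_for(master_seed, subject_index, "profile")
    weights = {
        band: max(0.02, w * (1.0 + 0.15 * rng.standard_normal()))
        for band, w in DEFAULT_BAND_WEIGHTS.items()
    }

    def draw_gain(lo: float, hi: float) -> float:
        if not gain_bimodal:
            return float(rng.uniform(lo, hi))
        width = 0.15 * (hi - lo)
        if subject_index % 2 == 0:
            return float(rng.uniform(hi - width, hi))
        return float(rng.uniform(lo, lo + width))

    def gains_for(carriers) -> dict[str, float]:
        return {c: 1.0 if c in carriers else uninformative_gain for c in CHANNELS}

    informative = tuple(informative_channels)
    if complementary and len(informative) >= 2:
        half = len(informative) // 2
        channel_gains = gains_for(informative[:half])
        channel_gains_mental = gains_for(informative[half:])
    else:
        channel_gains = gains_for(informative)
        channel_gains_mental = None
    return SubjectProfile(
        subject_id=f"sub{subject_index + 1:02d}",
        baseline_band_weights=weights,
        fatigue_gain_physical=draw_gain(*gain_physical_range),
        fatigue_gain_mental=draw_gain(*gain_mental_range),
        noise_scale=noise_scale,
        channel_gains=channel_gains,
        channel_gains_mental=channel_gains_mental,
        baseline_score=baseline_score,
    )


def generate_cohort(
    n_subjects: int = 12,
    plans: list[SessionPlan] | None = None,
    master_seed: int = 0,
    informative_channels=CHANNELS,
    uninformative_gain: float = 0.1,
    gain_physical_range: tuple[float, float] = (0.8, 1.6),
    gain_mental_range: tuple[float, float] = (0.8, 1.6),
    noise_scale: float = 0.3,
    oscillation_mode: str = "narrowband",
    complementary: bool = False,
    gain_bimodal: bool = False,
) -> Cohort:
    """Generate recordings plus scores for ``n_subjects`` x ``len(plans)``.

    Per-subject seeds are ``SeedSequence([master_seed, subject_index])``;
    identical inputs give identical cohorts.
    """
    if n_subjects < 2:
        raise ConfigurationError(
            f"need at least 2 subjects for subject-independent folds, got {n_subjects}"
        )
    if plans is None:
        plans = default_plans()
    if not plans:
        raise ConfigurationError("plans must be non-empty")

    profiles = [
        make_profile(
            i,
            master_seed,
            informative_channels=informative_channels,
            uninformative_gain=uninformative_gain,
            gain_physical_range=gain_physical_range,
            gain_mental_range=gain_mental_range,
            noise_scale=noise_scale,
            complementary=complementary,
            gain_bimodal=gain_bimodal,
        )
        for i in range(n_subjects)
    ]
    recordings: dict[tuple[str, int], Recording] = {}
    score_rows: list[dict] = []
    from eegfatigue._seeds import child_seed

    for i, profile in enumerate(profiles):
        for plan in plans:
            seed = child_seed(master_seed, i, plan.session_index)
            rec = generate_recording(profile, plan, seed, oscillation_mode)
            recordings[(profile.subject_id, plan.session_index)] = rec
            score_rows.extend(generate_scores(profile, plan, seed).to_rows())

    scores = pd.DataFrame(score_rows)
    manifest = {
        "n_subjects": n_subjects,
        "subjects": [p.subject_id for p in profiles],
        "sessions": [p.session_index for p in plans],
        "intensities": {p.session_index: p.intensity for p in plans},
        "event_durations_s": {
            p.session_index: dict(p.schedule.durations) for p in plans
        },
        "sampling_rate": plans[0].sampling_rate,
        "master_seed": int(master_seed),
        "seed_scheme": "SeedSequence([master_seed, subject_index, session_index])",
        "informative_channels": list(informative_channels),
        "complementary_signatures": complementary,
        "oscillation_mode": oscillation_mode,
    }
    return Cohort(
        profiles=profiles, plans=plans, recordings=recordings,
        scores=scores, manifest=manifest,
    )


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Write per-session recording CSVs, a scores CSV and the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (subject, session), rec in cohort.recordings.items():
        write_recording_csv(rec, outdir / f"{subject}_session{session}.csv")
    cohort.scores.to_csv(outdir / "scores.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(cohort.manifest, fh, indent=2, sort_keys=True)
    return outdir
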