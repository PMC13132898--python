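"""Shared constants: montage, sampling, windowing, feature naming."""

from __future__ import annotations

#: Headband montage, in canonical (left-to-right) order. All channel-keyed
#: structures in the package follow this order.
CHANNELS: tuple[str, ...] = ("TP9", "AF7", "AF8", "TP10")

#: Samples per second of the recordings.
SAMPLING_RATE: int = 256

#: Length of one analysis window.
WINDOW_SECONDS: int = 10
WINDOW_SAMPLES: int = SAMPLING_RATE * WINDOW_SECONDS  # 2560

#: Ordered event schedule of one session. ``s*`` are task events
#: (baseline / physical / mental), ``m*`` are measurement probes.
EVENTS: tuple[str, ...] = ("s1", "m1", "s2", "m2", "s3", "m3")

#: Events that contribute rows to the modelling table.
TASK_EVENTS: tuple[str, ...] = ("s1", "s2", "s3")

#: Task context recorded with each modelling row.
TASK_CONTEXT: dict[str, str] = {"s1": "baseline", "s2": "physical", "s3": "mental"}
CONTEXTS: tuple[str, ...] = ("baseline", "physical", "mental")

#: Frequency bands as (name, f_low, f_high); integration uses the
#: half-open interval [f_low, f_high) so shared edges are never counted twice.
BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 0.4, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta", 12.0, 30.0),
)

#: The 16 features, in the fixed order used everywhere.
FEATURE_NAMES: tuple[str, ...] = (
    "Mean",
    "SD",
    "Kur",
    "SK",
    "SE",
    "FE",
    "SnE",
    "RE",
    "PE",
    "DE",
    "SVDE",
    "delta_power",
    "theta_power",
    "alpha_power",
    "beta_power",
    "SpE",
)

FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "statistical": ("Mean", "SD", "Kur", "SK"),
    "entropy": ("SE", "FE", "SnE", "RE", "PE", "DE", "SVDE"),
    "frequency": ("delta_power", "theta_power", "alpha_power", "beta_power", "SpE"),
}


def feature_columns(channels) -> list[str]:
    """Column names of the per-channel feature blocks, channel-major."""
    return [f"{ch}_{name}" for ch in channels for name in FEATURE_NAMES]


def canonical_channels(channels) -> tuple[str, ...]:
    """Return ``channels`` sorted into canonical montage order."""
    unknown = [c for c in channels if c not in CHANNELS]
    if unknown:
        raise ValueError(f"unknown channel(s): {unknown}; expected subset of {CHANNELS}")
    return tuple(c for c in CHANNELS if c in set(channels))
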