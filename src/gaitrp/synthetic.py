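"""Synthetic vGRF cohort generator.

Produces labeled two-channel gait force traces with the statistical
structure the downstream pipeline assumes: double-peaked stance bursts
alternating with near-zero swing intervals, class-specific stride
regularity (HC most regular, HD least), prolonged stance for ALS and
stance duration approaching swing duration for HD.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from gaitrp.records import GaitRecord, LABELS


@dataclass(frozen=True)
class ClassProfile:
    """Gait parameters of one diagnostic class.

    ``stride_mean``/``stride_cv`` parameterize the lognormal law of
    per-stride durations; ``stance_fraction_mean``/``stance_fraction_cv``
    the fraction of each stride spent in stance; ``double_peak_depth``
    the relative depth of the valley between the loading and push-off
    peaks of the stance pulse.
    """

    label: str
    stride_mean: float = 1.1
    stride_cv: float = 0.03
    stance_fraction_mean: float = 0.62
    stance_fraction_cv: float = 0.02
    peak_amplitude: float = 1.0
    double_peak_depth: float = 0.3
    swing_noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.stride_mean <= 0:
            raise ValueError("stride_mean must be positive")
        if not 0.0 < self.stance_fraction_mean < 1.0:
            raise ValueError("stance_fraction_mean must be in (0, 1)")
        if self.stride_cv < 0 or self.stance_fraction_cv < 0:
            raise ValueError("coefficients of variation must be nonnegative")
        if not 0.0 <= self.double_peak_depth <= 1.0:
            raise ValueError("double_peak_depth must be in [0, 1]")
        if self.swing_noise_sd < 0:
            raise ValueError("swing_noise_sd must be nonnegative")


#: Default per-class profiles. Interval irregularity is strictly ordered
#: HC < ALS < PD < HD; ALS has the longest stance fraction and the most
#: pronounced double peak; HD stance fraction sits near 0.5 so stance and
#: swing durations are similar.
DEFAULT_PROFILES: dict[str, ClassProfile] = {
    "HC": ClassProfile(
        label="HC", stride_mean=1.05, stride_cv=0.02,
        stance_fraction_mean=0.62, stance_fraction_cv=0.02,
        peak_amplitude=1.0, double_peak_depth=0.25, swing_noise_sd=0.004,
    ),
    "ALS": ClassProfile(
        label="ALS", stride_mean=1.45, stride_cv=0.06,
        stance_fraction_mean=0.74, stance_fraction_cv=0.04,
        peak_amplitude=1.0, double_peak_depth=0.6, swing_noise_sd=0.006,
    ),
    "PD": ClassProfile(
        label="PD", stride_mean=0.95, stride_cv=0.14,
        stance_fraction_mean=0.64, stance_fraction_cv=0.10,
        peak_amplitude=1.0, double_peak_depth=0.15, swing_noise_sd=0.006,
    ),
    "HD": ClassProfile(
        label="HD", stride_mean=1.15, stride_cv=0.26,
        stance_fraction_mean=0.50, stance_fraction_cv=0.15,
        peak_amplitude=1.0, double_peak_depth=0.5, swing_noise_sd=0.008,
    ),
}


@dataclass
class SimulationConfig:
    """Cohort-level simulation settings."""

    duration: float = 300.0
    sampling_rate: float = 300.0
    subjects_per_class: int = 4
    seed: int = 0
    profiles: dict[str, ClassProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )

    def __post_init__(self) -> None:
        n = self.duration * self.sampling_rate
        if n <= 0 or abs(n - round(n)) > 1e-6:
            raise ValueError(
                "duration x sampling_rate must be a positive integer "
                f"sample count, got {n}"
            )
        if self.subjects_per_class < 1:
            raise ValueError("subjects_per_class must be >= 1")


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    # mu/sigma of a lognormal with given arithmetic mean and CV
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _stance_pulse(n: int, depth: float, amplitude: float) -> np.ndarray:
    """Double-peaked stance pulse of ``n`` samples.

    Sum of two Gaussian bumps centered at 25% and 75% of stance; the bump
    width is solved so the mid-stance valley sits at (1 - depth) of the
    peak value, then the pulse is rescaled to ``amplitude``.
    """
    if n < 1:
        return np.zeros(0)
    t = np.linspace(0.0, 1.0, n)
    c1, c2 = 0.25, 0.75
    a = (c2 - c1) / 2.0  # half peak separation
    r = np.clip(1.0 - depth, 0.05, 1.0)  # target valley / peak ratio
    # valley = 2 exp(-a^2 / 2 s^2) with unit peaks; invert for s
    s = a / np.sqrt(2.0 * np.log(2.0 / r))
    pulse = np.exp(-0.5 * ((t - c1) / s) ** 2) + np.exp(-0.5 * ((t - c2) / s) ** 2)
    pulse *= amplitude / pulse.max()
    return pulse


def _foot_events(
    rng: np.random.Generator,
    profile: ClassProfile,
    duration: float,
    t0: float,
) -> list[tuple[float, float]]:
    """Draw (stance_start, stance_duration) events for one foot starting
    at time ``t0`` and covering ``duration`` seconds."""
    mu_s, sg_s = _lognormal_params(profile.stride_mean, profile.stride_cv)
    events = []
    t = t0
    while t < duration:
        stride = rng.lognormal(mu_s, sg_s)
        frac = profile.stance_fraction_mean
        if profile.stance_fraction_cv > 0:
            frac = rng.normal(frac, profile.stance_fraction_cv * frac)
        frac = float(np.clip(frac, 0.05, 0.95))
        events.append((t, stride * frac))
        t += stride
    return events


def generate_subject(
    profile: ClassProfile,
    duration: float,
    fs: float,
    seed: int,
    subject_id: str | None = None,
) -> GaitRecord:
    """Simulate one subject's two-channel vGRF trace.

    The left foot walks with i.i.d. lognormal stride intervals; each
    stance occupies a drawn fraction of its stride and is rendered as a
    double-peaked pulse. The right foot runs in antiphase: each right
    stance begins near the middle of the corresponding left stride, with
    the offset jittered by the profile's stride CV. Swing intervals carry
    small nonnegative sensor noise.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if duration < profile.stride_mean:
        raise ValueError(
            f"duration {duration} s is shorter than one mean stride "
            f"({profile.stride_mean} s)"
        )
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)

    left = np.zeros(n)
    right = np.zeros(n)

    left_events = _foot_events(rng, profile, duration, t0=0.0)
    # right stance begins near mid-left-stride, jittered per stride
    right_events = []
    mu_s, sg_s = _lognormal_params(profile.stride_mean, profile.stride_cv)
    for k, (t_l, _) in enumerate(left_events):
        t_next = left_events[k + 1][0] if k + 1 < len(left_events) else duration
        stride_l = t_next - t_l
        jitter = rng.normal(0.0, profile.stride_cv) if profile.stride_cv > 0 else 0.0
        t_r = t_l + stride_l * (0.5 + 0.5 * jitter)
        frac = profile.stance_fraction_mean
        if profile.stance_fraction_cv > 0:
            frac = rng.normal(frac, profile.stance_fraction_cv * frac)
        frac = float(np.clip(frac, 0.05, 0.95))
        right_events.append((t_r, stride_l * frac))

    for channel, events in ((left, left_events), (right, right_events)):
        for t_start, stance in events:
            i0 = int(round(t_start * fs))
            i1 = min(int(round((t_start + stance) * fs)), n)
            if i1 <= i0 or i0 >= n:
                continue
            pulse = _stance_pulse(i1 - i0, profile.double_peak_depth,
                                  profile.peak_amplitude)
            channel[i0:i1] = np.maximum(channel[i0:i1], pulse)

    if profile.swing_noise_sd > 0:
        left += rng.normal(0.0, profile.swing_noise_sd, n)
        right += rng.normal(0.0, profile.swing_noise_sd, n)
    np.clip(left, 0.0, None, out=left)
    np.clip(right, 0.0, None, out=right)

    time = np.arange(n) / fs
    return GaitRecord(
        subject_id=subject_id or f"{profile.label}-{seed}",
        label=profile.label,
        fs=fs,
        time=time,
        left=left,
        right=right,
        meta={"seed": seed},
    )


def generate_cohort(config: SimulationConfig) -> list[GaitRecord]:
    """Simulate ``subjects_per_class`` records per label.

    Per-subject seeds are spawned deterministically from ``config.seed``
    via :class:`numpy.random.SeedSequence`, so identical configs yield
    bit-identical cohorts.
    """
    records = []
    labels = [lab for lab in LABELS if lab in config.profiles]
    for ci, label in enumerate(labels):
        profile = config.profiles[label]
        for si in range(config.subjects_per_class):
            ss = np.random.SeedSequence(config.seed, spawn_key=(ci, si))
            sub_seed = int(ss.generate_state(1)[0])
            records.append(
                generate_subject(
                    profile,
                    config.duration,
                    config.sampling_rate,
                    seed=sub_seed,
                    subject_id=f"{label}{si + 1:02d}",
                )
            )
    return records


def write_cohort(records: list[GaitRecord], out_dir: str | Path,
                 config: SimulationConfig | None = None) -> Path:
    """Write one three-column text file per subject plus a CSV manifest.

    Returns the manifest path.
    """
    from gaitrp.io import write_record

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    fields = ["subject_id", "label", "fs", "path", "seed"]
    profile_fields = [f.name for f in ClassProfile.__dataclass_fields__.values()
                      if f.name != "label"]
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(fields + profile_fields)
        for rec in records:
            path = out_dir / f"{rec.subject_id}.txt"
            write_record(path, rec)
            prof = (config.profiles.get(rec.label) if config else None)
            prow = [getattr(prof, f) if prof else "" for f in profile_fields]
            writer.writerow(
                [rec.subject_id, rec.label, rec.fs, path.name,
                 rec.meta.get("seed", "")] + prow
            )
    return manifest
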