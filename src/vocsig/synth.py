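"""Synthetic cat-call generator with known ground-truth individual structure.

Two waveform families are produced:

* **meow** — a tonal, harmonically structured call (F0 roughly 208-1000 Hz,
  typical duration well under 2.5 s).  Modelled as an additive harmonic
  source with a -12 dB/octave spectral tilt, shaped by two resonance bumps
  (a crude vocal-tract filter) and an open-then-closing-mouth amplitude
  envelope.
* **purr** — a continuous low-frequency pulse train (F0 25-30 Hz, durations
  of seconds to tens of seconds) produced on alternating egressive and
  ingressive airstreams.  Modelled as periodic damped noise bursts passed
  through an individual-specific resonance, with a slow (~1 Hz)
  alternating amplitude modulation emulating the two breathing phases.

Individuality is injected at two levels: each individual gets a profile
(mean F0, resonance placement, mean duration, ...) drawn around the call
type's base values with a spread proportional to ``between_sd_scale``; each
call then jitters around its individual's profile with a spread
proportional to ``within_sd_scale``.  The ratio of the two scales controls
how much identity information downstream stages can recover.

All randomness flows from a single :class:`numpy.random.Generator` seeded
from :class:`CohortSpec.seed`; profile sampling consumes the stream before
any call synthesis, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "IndividualProfile",
    "CohortSpec",
    "CallRecording",
    "sample_individual_profiles",
    "synthesize_meow",
    "synthesize_purr",
    "synthesize_call",
    "generate_cohort",
    "generate_species_cohort",
    "write_cohort",
    "MEOW_BASE",
    "PURR_BASE",
]

MEOW_F0_RANGE = (150.0, 1200.0)
MEOW_DURATION_RANGE = (0.17, 2.21)
PURR_F0_RANGE = (20.0, 40.0)
PURR_DURATION_RANGE = (1.09, 39.82)

# Base (population-level) parameters per call type.  Means follow the
# published descriptive statistics for domestic cats (meow F0 centred in the
# 208-1000 Hz band, mean duration 0.72 s; purr F0 25-30 Hz, mean duration
# 10.77 s); spreads are the unit-scale between/within standard deviations
# multiplied by CohortSpec.between_sd_scale / within_sd_scale.
MEOW_BASE = {
    "f0_mean": 450.0,
    "f0_between_sd": 80.0,
    "f0_jitter_sd": 30.0,
    "formant_centers": (950.0, 2800.0),
    "formant_between_sd": (120.0, 220.0),
    "formant_bandwidths": (160.0, 260.0),
    "duration_mean": 0.72,
    "duration_between_sd": 0.25,
    "duration_sd": 0.12,
    "spectral_jitter_sd": 40.0,
}

PURR_BASE = {
    "f0_mean": 27.5,
    "f0_between_sd": 2.0,
    "f0_jitter_sd": 1.0,
    "burst_center": 400.0,
    "burst_between_sd": 90.0,
    "burst_bandwidth": 150.0,
    "duration_mean": 10.77,
    "duration_between_sd": 2.5,
    "duration_sd": 1.5,
    "duty_mean": 0.35,
    "duty_between_sd": 0.06,
    "asym_mean": 0.70,
    "asym_between_sd": 0.08,
    "spectral_jitter_sd": 25.0,
}

#: Amplitude boost at a resonance centre relative to the tilted source.
#: Kept below 3 so that, combined with the k**-2 source tilt, the
#: fundamental is always the largest spectral peak below the first formant.
_FORMANT_PEAK_GAIN = 2.5

#: Breathing (egressive/ingressive alternation) rate for purrs, Hz.
_BREATH_RATE_HZ = 0.9


class SynthesisError(ValueError):
    """Invalid profile/spec parameter for call synthesis."""


@dataclass(frozen=True)
class IndividualProfile:
    """Ground-truth acoustic identity of one synthetic individual."""

    individual_id: str
    call_type: str  # "meow" | "purr"
    f0_mean: float
    f0_jitter_sd: float
    duration_mean: float
    duration_sd: float
    formant_centers: tuple[float, ...] = ()  # meow only
    formant_bandwidths: tuple[float, ...] = ()  # meow only
    pulse_duty_cycle: float = 0.0  # purr only, fraction of a period
    envelope_asymmetry: float = 1.0  # purr only, ingressive/egressive gain
    burst_center: float = 0.0  # purr only, Hz
    burst_bandwidth: float = 0.0  # purr only, Hz
    spectral_jitter_sd: float = 0.0  # per-call wobble of resonances, Hz

    def validate(self, sample_rate: float | None = None) -> None:
        if self.call_type not in ("meow", "purr"):
            raise SynthesisError(f"call_type must be 'meow' or 'purr', got {self.call_type!r}")
        if self.f0_mean <= 0:
            raise SynthesisError("f0_mean must be > 0")
        if self.duration_mean <= 0:
            raise SynthesisError("duration_mean must be > 0")
        if self.call_type == "meow":
            lo, hi = MEOW_F0_RANGE
            if not (lo <= self.f0_mean <= hi):
                raise SynthesisError(f"meow f0_mean {self.f0_mean} outside [{lo}, {hi}] Hz")
            if list(self.formant_centers) != sorted(self.formant_centers):
                raise SynthesisError("formant_centers must be strictly increasing")
            if sample_rate is not None and self.formant_centers and max(
                self.formant_centers
            ) >= sample_rate / 2:
                raise SynthesisError("formant_centers must lie below the Nyquist frequency")
        else:
            lo, hi = PURR_F0_RANGE
            if not (lo <= self.f0_mean <= hi):
                raise SynthesisError(f"purr f0_mean {self.f0_mean} outside [{lo}, {hi}] Hz")
            if not (0.0 < self.pulse_duty_cycle < 1.0):
                raise SynthesisError("pulse_duty_cycle must be in (0, 1)")
            if not (0.0 <= self.envelope_asymmetry <= 1.0):
                raise SynthesisError("envelope_asymmetry must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort of labelled calls.

    ``between_sd_scale`` multiplies the spread of profile means across
    individuals; ``within_sd_scale`` multiplies per-call jitter around each
    profile.  Both default to 1, the unit study-like condition.
    """

    n_individuals: int
    calls_per_individual: int
    call_type: str
    between_sd_scale: float = 1.0
    within_sd_scale: float = 1.0
    sample_rate: float = 96_000.0
    seed: int = 0
    species_id: str = "F_catus"

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise SynthesisError("n_individuals must be >= 2")
        if self.calls_per_individual < 2:
            raise SynthesisError("calls_per_individual must be >= 2")
        if self.call_type not in ("meow", "purr"):
            raise SynthesisError(f"call_type must be 'meow' or 'purr', got {self.call_type!r}")
        if self.between_sd_scale < 0:
            raise SynthesisError("between_sd_scale must be >= 0")
        if self.within_sd_scale < 0:
            raise SynthesisError("within_sd_scale must be >= 0")
        base = MEOW_BASE if self.call_type == "meow" else PURR_BASE
        if self.call_type == "meow":
            highest = max(base["formant_centers"]) + 4 * base["formant_between_sd"][-1]
        else:
            highest = base["burst_center"] + 4 * base["burst_between_sd"] + base["burst_bandwidth"]
        if self.sample_rate <= 2 * highest:
            raise SynthesisError(
                f"sample_rate {self.sample_rate} must exceed twice the highest "
                f"synthesized frequency (~{highest:.0f} Hz)"
            )


@dataclass
class CallRecording:
    """A single call's waveform plus its labels."""

    samples: np.ndarray
    sample_rate: float
    individual_id: str = ""
    species_id: str = ""
    call_type: str = ""

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.sample_rate

    def validate(self) -> None:
        if self.samples.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains NaN/Inf samples")
        if np.max(np.abs(self.samples)) > 1.0 + 1e-9:
            raise ValueError("samples must lie in [-1, 1]")


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    """Gaussian draw clipped to [lo, hi] (simple truncation by clipping)."""
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def sample_individual_profiles(
    spec: CohortSpec, rng: np.random.Generator
) -> list[IndividualProfile]:
    """Draw ``spec.n_individuals`` identity profiles for one cohort.

    Profile means are drawn around the call type's base values with spread
    ``between_sd_scale * base_between_sd``; per-call jitter SDs are the base
    within-SDs times ``within_sd_scale``.  With ``between_sd_scale == 0``
    every profile is identical apart from its label.
    """
    spec.validate()
    b = spec.between_sd_scale
    w = spec.within_sd_scale
    profiles: list[IndividualProfile] = []
    for i in range(spec.n_individuals):
        ind_id = f"{spec.call_type}_ind{i:02d}"
        if spec.call_type == "meow":
            p = MEOW_BASE
            f0 = float(_truncnorm(rng, p["f0_mean"], b * p["f0_between_sd"], *MEOW_F0_RANGE))
            centers = []
            prev = 0.0
            for c0, csd in zip(p["formant_centers"], p["formant_between_sd"]):
                c = float(
                    _truncnorm(rng, c0, b * csd, max(prev + 100.0, 0.4 * c0), 0.45 * spec.sample_rate)
                )
                centers.append(c)
                prev = c
            dur = float(
                _truncnorm(rng, p["duration_mean"], b * p["duration_between_sd"], *MEOW_DURATION_RANGE)
            )
            prof = IndividualProfile(
                individual_id=ind_id,
                call_type="meow",
                f0_mean=f0,
                f0_jitter_sd=w * p["f0_jitter_sd"],
                duration_mean=dur,
                duration_sd=w * p["duration_sd"],
                formant_centers=tuple(centers),
                formant_bandwidths=tuple(p["formant_bandwidths"]),
                spectral_jitter_sd=w * p["spectral_jitter_sd"],
            )
        else:
            p = PURR_BASE
            f0 = float(_truncnorm(rng, p["f0_mean"], b * p["f0_between_sd"], *PURR_F0_RANGE))
            dur = float(
                _truncnorm(rng, p["duration_mean"], b * p["duration_between_sd"], *PURR_DURATION_RANGE)
            )
            burst = float(
                _truncnorm(rng, p["burst_center"], b * p["burst_between_sd"], 80.0, 0.4 * spec.sample_rate)
            )
            duty = float(_truncnorm(rng, p["duty_mean"], b * p["duty_between_sd"], 0.05, 0.9))
            asym = float(_truncnorm(rng, p["asym_mean"], b * p["asym_between_sd"], 0.05, 1.0))
            prof = IndividualProfile(
                individual_id=ind_id,
                call_type="purr",
                f0_mean=f0,
                f0_jitter_sd=w * p["f0_jitter_sd"],
                duration_mean=dur,
                duration_sd=w * p["duration_sd"],
                pulse_duty_cycle=duty,
                envelope_asymmetry=asym,
                burst_center=burst,
                burst_bandwidth=p["burst_bandwidth"],
                spectral_jitter_sd=w * p["spectral_jitter_sd"],
            )
        prof.validate(spec.sample_rate)
        profiles.append(prof)
    return profiles


def _meow_envelope(n: int) -> np.ndarray:
    # Open-then-closing-mouth amplitude contour: fast half-cosine attack,
    # slower half-cosine release, sustained in between.
    attack = max(2, int(0.15 * n))
    release = max(2, int(0.30 * n))
    env = np.ones(n)
    env[:attack] = 0.5 * (1 - np.cos(np.pi * np.arange(attack) / attack))
    env[n - release:] = 0.5 * (1 + np.cos(np.pi * np.arange(release) / release))
    return env


def synthesize_meow(
    profile: IndividualProfile, rng: np.random.Generator, sample_rate: float
) -> CallRecording:
    """Render one meow from an individual profile.

    The source is a harmonic stack at the per-call F0 with amplitudes
    ``k**-2 * (1 + g * sum_j exp(-(f_k - F_j)^2 / 2 bw_j^2))`` — a spectral
    tilt shaped by Gaussian resonance bumps at the (per-call jittered)
    formant centres.  At the default gain the fundamental remains the
    largest spectral peak below the first formant.
    """
    profile.validate(sample_rate)
    if profile.call_type != "meow":
        raise SynthesisError("synthesize_meow requires a meow profile")
    nyquist = sample_rate / 2.0
    f0 = float(_truncnorm(rng, profile.f0_mean, profile.f0_jitter_sd, *MEOW_F0_RANGE))
    dur = float(
        _truncnorm(rng, profile.duration_mean, profile.duration_sd, *MEOW_DURATION_RANGE)
    )
    centers = np.asarray(profile.formant_centers, dtype=float)
    if profile.spectral_jitter_sd > 0:
        centers = centers + rng.normal(0.0, profile.spectral_jitter_sd, size=centers.shape)
    if np.any(centers >= nyquist):
        raise SynthesisError("formant centre at or above Nyquist frequency")
    bws = np.asarray(profile.formant_bandwidths, dtype=float)

    n = int(round(dur * sample_rate))
    t = np.arange(n) / sample_rate
    n_harm = max(5, int(0.45 * sample_rate / f0))
    k = np.arange(1, n_harm + 1)
    fk = k * f0
    keep = fk < 0.95 * nyquist
    k, fk = k[keep], fk[keep]
    gains = 1.0 + _FORMANT_PEAK_GAIN * np.sum(
        np.exp(-((fk[:, None] - centers[None, :]) ** 2) / (2.0 * bws[None, :] ** 2)), axis=1
    )
    amps = gains * k.astype(float) ** -2.0
    wave = np.sin(2 * np.pi * fk[None, :] * t[:, None]) @ amps
    wave *= _meow_envelope(n)
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave *= 0.95 / peak
    return CallRecording(wave, sample_rate, profile.individual_id, "", "meow")


def synthesize_purr(
    profile: IndividualProfile, rng: np.random.Generator, sample_rate: float
) -> CallRecording:
    """Render one purr from an individual profile.

    A pulse train at the per-call F0 (20-40 Hz): each pulse is an
    exponentially damped noise burst occupying ``pulse_duty_cycle`` of a
    period; the assembled train is passed through a two-pole resonance at
    the individual's burst centre, then amplitude-modulated by an
    alternating egressive/ingressive gain (1 vs ``envelope_asymmetry``) at
    ~0.9 Hz.
    """
    profile.validate(sample_rate)
    if profile.call_type != "purr":
        raise SynthesisError("synthesize_purr requires a purr profile")
    if not (0.0 < profile.pulse_duty_cycle < 1.0):
        raise SynthesisError("pulse_duty_cycle must be in (0, 1)")
    f0 = float(_truncnorm(rng, profile.f0_mean, profile.f0_jitter_sd, *PURR_F0_RANGE))
    dur = float(
        _truncnorm(rng, profile.duration_mean, profile.duration_sd, *PURR_DURATION_RANGE)
    )
    center = profile.burst_center
    if profile.spectral_jitter_sd > 0:
        center = float(rng.normal(center, profile.spectral_jitter_sd))
    center = float(np.clip(center, 60.0, 0.45 * sample_rate))

    n = int(round(dur * sample_rate))
    period = sample_rate / f0
    pulse_len = max(4, int(round(profile.pulse_duty_cycle * period)))
    decay = np.exp(-4.0 * np.arange(pulse_len) / pulse_len)

    wave = np.zeros(n)
    i = 0
    while True:
        onset = int(round(i * period))
        if onset >= n:
            break
        m = min(pulse_len, n - onset)
        wave[onset : onset + m] += decay[:m] * rng.standard_normal(m)
        i += 1

    # individual-specific spectral envelope: two-pole peak filter
    q = max(0.5, center / profile.burst_bandwidth)
    b, a = sps.iirpeak(center, q, fs=sample_rate)
    wave = sps.lfilter(b, a, wave)

    # alternating egressive (gain 1) / ingressive (gain = asymmetry) phases
    t = np.arange(n) / sample_rate
    half = np.floor(2.0 * _BREATH_RATE_HZ * t).astype(int) % 2
    gain = np.where(half == 0, 1.0, profile.envelope_asymmetry)
    wave = wave * gain

    peak = np.max(np.abs(wave))
    if peak > 0:
        wave *= 0.95 / peak
    return CallRecording(wave, sample_rate, profile.individual_id, "", "purr")


def synthesize_call(
    profile: IndividualProfile, rng: np.random.Generator, sample_rate: float
) -> CallRecording:
    if profile.call_type == "meow":
        return synthesize_meow(profile, rng, sample_rate)
    return synthesize_purr(profile, rng, sample_rate)


def generate_cohort(spec: CohortSpec) -> list[CallRecording]:
    """Generate ``n_individuals x calls_per_individual`` labelled recordings.

    A single RNG stream is seeded from ``spec.seed``; profile sampling
    consumes it first, then calls are synthesized individual by individual
    in label order, so output is byte-reproducible.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    profiles = sample_individual_profiles(spec, rng)
    recordings: list[CallRecording] = []
    for prof in profiles:
        for _ in range(spec.calls_per_individual):
            rec = synthesize_call(prof, rng, spec.sample_rate)
            rec.species_id = spec.species_id
            rec.validate()
            recordings.append(rec)
    return recordings


def generate_species_cohort(
    n_species: int,
    calls_per_species: int,
    within_scales: Sequence[float],
    between_sd_scale: float = 2.0,
    sample_rate: float = 16_000.0,
    seed: int = 0,
) -> list[CallRecording]:
    """Meow cohort with one profile per *species* and per-species within-scales.

    Emulates the cross-species comparison design: species separated by
    ``between_sd_scale``, with species ``s`` jittering per call at
    ``within_scales[s]`` times the base within-SD.  Used to test that a
    species with inflated within-variance shows the largest signal-space
    dispersion.
    """
    if len(within_scales) != n_species:
        raise SynthesisError("within_scales must have one entry per species")
    spec = CohortSpec(
        n_individuals=n_species,
        calls_per_individual=calls_per_species,
        call_type="meow",
        between_sd_scale=between_sd_scale,
        within_sd_scale=1.0,
        sample_rate=sample_rate,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    base_profiles = sample_individual_profiles(spec, rng)
    recordings: list[CallRecording] = []
    for s, prof in enumerate(base_profiles):
        w = float(within_scales[s])
        sp_prof = replace(
            prof,
            individual_id=f"species{s:02d}_ind00",
            f0_jitter_sd=prof.f0_jitter_sd * w,
            duration_sd=prof.duration_sd * w,
            spectral_jitter_sd=prof.spectral_jitter_sd * w,
        )
        for _ in range(calls_per_species):
            rec = synthesize_call(sp_prof, rng, sample_rate)
            rec.species_id = f"species{s:02d}"
            rec.validate()
            recordings.append(rec)
    return recordings


def write_cohort(
    recordings: Sequence[CallRecording], out_dir: str | Path, seed: int | None = None
) -> Path:
    """Write one 16-bit PCM WAV per call plus a manifest CSV.

    Returns the manifest path.  Manifest columns: file, individual_id,
    species_id, call_type, seed.
    """
    from .features import write_wav  # local import to avoid cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "individual_id", "species_id", "call_type", "seed"])
        for i, rec in enumerate(recordings):
            name = f"call_{i:04d}_{rec.call_type}_{rec.individual_id}.wav"
            write_wav(out_dir / name, rec)
            writer.writerow([name, rec.individual_id, rec.species_id, rec.call_type, seed])
    return manifest
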