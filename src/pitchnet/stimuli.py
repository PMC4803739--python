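"""Synthesis of pitch-evoking sound stimuli.

Three stimulus families are supported, all parameterised by a fundamental
frequency F0:

* **harmonic** complexes — a sum of sinusoids at ``k*F0`` for
  ``k = 1..n_harmonics`` (a *pure* tone is the ``k = 1`` special case);
* **missing-fundamental** (MF) complexes — the same sum with the F0
  component removed (``k = 2..n_harmonics``), which listeners still hear
  at the pitch of F0;
* **iterated rippled noise** (IRN) — broadband noise repeatedly delayed by
  one pitch period ``1/F0`` and added to itself, which acquires a pitch at
  F0 as the iteration count grows.

Harmonic amplitudes may decay with component frequency ``f`` as
``exp(-f / tau)``; ``tau = None`` means a flat (constant-amplitude)
profile.  Waveforms are calibrated to a sound pressure level in dB SPL
(re 20 uPa RMS) with raised-cosine onset/offset ramps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.io import wavfile

__all__ = [
    "StimulusSpec",
    "Waveform",
    "KINDS",
    "P_REF",
    "make_harmonic_complex",
    "make_irn",
    "synthesize",
    "calibrate",
    "make_training_set",
    "sample_random_tau",
    "harmonic_amplitudes",
    "write_wav",
    "read_wav",
    "specs_to_manifest",
]

#: Reference pressure for dB SPL, in pascal.
P_REF = 20e-6

KINDS = ("pure", "harmonic", "missing_fundamental", "irn")

_TONAL_KINDS = ("pure", "harmonic", "missing_fundamental")


@dataclass(frozen=True)
class StimulusSpec:
    """Declarative description of one sound stimulus.

    Parameters
    ----------
    kind
        One of ``"pure"``, ``"harmonic"``, ``"missing_fundamental"``,
        ``"irn"``.
    f0
        Fundamental frequency in Hz (for IRN: the reciprocal of the
        delay-and-add lag).
    n_harmonics
        Number of harmonics counted from and including F0.  Ignored for
        ``pure`` (always 1) and ``irn``.
    tau
        Harmonic decay constant in Hz: component at frequency ``f`` is
        scaled by ``exp(-f / tau)``.  ``None`` means a flat profile.
    irn_iterations
        Number of delay-and-add iterations for IRN stimuli.
    level_db_spl
        Calibration level in dB SPL re 20 uPa RMS.
    duration, ramp, sample_rate
        Stimulus length (s), raised-cosine ramp length (s) and sampling
        rate (Hz).
    noise_seed
        Seed for the IRN noise carrier; required for reproducible IRNs.
    """

    kind: str
    f0: float
    n_harmonics: int = 10
    tau: float | None = None
    irn_iterations: int = 30
    level_db_spl: float = 50.0
    duration: float = 0.2
    ramp: float = 0.01
    sample_rate: float = 50_000.0
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if not self.f0 > 0:
            raise ValueError("f0 must be positive")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.tau is not None and not self.tau > 0:
            raise ValueError("tau must be positive or None (flat)")
        if self.irn_iterations < 0:
            raise ValueError("irn_iterations must be >= 0")
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if self.ramp < 0 or 2 * self.ramp > self.duration:
            raise ValueError("need 0 <= 2*ramp <= duration")
        if self.kind in ("harmonic", "missing_fundamental"):
            # Highest component must sit below Nyquist with headroom.
            if 2 * self.n_harmonics * self.f0 >= self.sample_rate:
                raise ValueError(
                    f"highest harmonic {self.n_harmonics * self.f0:g} Hz "
                    f"exceeds Nyquist headroom at fs={self.sample_rate:g} Hz"
                )

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.sample_rate)

    @property
    def harmonic_numbers(self) -> tuple[int, ...]:
        """Included harmonic indices k (components at k*f0)."""
        if self.kind == "pure":
            return (1,)
        if self.kind == "harmonic":
            return tuple(range(1, self.n_harmonics + 1))
        if self.kind == "missing_fundamental":
            return tuple(range(2, self.n_harmonics + 1))
        raise ValueError("IRN stimuli have no discrete harmonic set")


@dataclass(frozen=True)
class Waveform:
    """A sampled pressure signal."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float64)
        )
        if self.samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


def harmonic_amplitudes(spec: StimulusSpec) -> np.ndarray:
    """Component amplitudes exp(-k*f0/tau) for the included harmonics.

    A flat profile (``tau=None``) gives all-equal amplitudes.  The decay
    is applied to every included component, F0 itself included.
    """
    ks = np.asarray(spec.harmonic_numbers, dtype=float)
    if spec.tau is None:
        return np.ones_like(ks)
    return np.exp(-ks * spec.f0 / spec.tau)


def make_harmonic_complex(spec: StimulusSpec) -> Waveform:
    """Synthesize a (possibly missing-fundamental) harmonic complex.

    Components are sine-phase with amplitudes from
    :func:`harmonic_amplitudes`.  The output is *not* yet calibrated or
    ramped; see :func:`calibrate`.
    """
    if spec.kind not in _TONAL_KINDS:
        raise ValueError(f"not a tonal stimulus kind: {spec.kind!r}")
    t = np.arange(spec.n_samples) / spec.sample_rate
    amps = harmonic_amplitudes(spec)
    ks = np.asarray(spec.harmonic_numbers, dtype=float)
    # (n_harm, n_samples) sinusoid bank summed over components.
    phases = 2.0 * np.pi * spec.f0 * np.outer(ks, t)
    samples = amps @ np.sin(phases)
    return Waveform(samples, spec.sample_rate)


def make_irn(
    spec: StimulusSpec,
    rng: np.random.Generator | None = None,
    *,
    variant: str = "add_same",
) -> Waveform:
    """Synthesize iterated rippled noise by delay-and-add.

    Gaussian broadband noise is delayed by one pitch period ``1/f0``
    (rounded to the nearest whole sample) and added to the running signal,
    repeated ``irn_iterations`` times.  ``variant="add_same"`` feeds the
    accumulated signal back into the delay each iteration;
    ``"add_original"`` always delays the original noise.  Zero iterations
    return the raw noise.  Deterministic given ``noise_seed``.
    """
    if spec.kind != "irn":
        raise ValueError("spec.kind must be 'irn'")
    if variant not in ("add_same", "add_original"):
        raise ValueError(f"unknown IRN variant {variant!r}")
    delay = round(spec.sample_rate / spec.f0)
    if delay < 1:
        raise ValueError(
            f"IRN delay 1/f0 = {1 / spec.f0:g} s is shorter than one sample "
            f"at fs={spec.sample_rate:g} Hz"
        )
    if rng is None:
        rng = np.random.default_rng(spec.noise_seed)
    noise = rng.standard_normal(spec.n_samples)
    out = noise.copy()
    for _ in range(spec.irn_iterations):
        src = out if variant == "add_same" else noise
        delayed = np.zeros_like(out)
        delayed[delay:] = src[:-delay]
        out = out + delayed
    return Waveform(out, spec.sample_rate)


def calibrate(
    w: Waveform, level_db_spl: float, ramp: float
) -> Waveform:
    """Scale a waveform to a dB SPL level and apply cosine ramps.

    The scaling is chosen so the RMS of the *central un-ramped* portion
    equals ``P_REF * 10**(level/20)`` pascal; raised-cosine onset and
    offset envelopes of length ``ramp`` seconds are then applied, so the
    first and last samples are exactly zero for any positive ramp.
    """
    n = w.samples.size
    n_ramp = round(ramp * w.sample_rate)
    if n_ramp < 0 or 2 * n_ramp > n:
        raise ValueError("need 0 <= 2*ramp <= duration")
    core = w.samples[n_ramp : n - n_ramp] if n_ramp else w.samples
    rms = float(np.sqrt(np.mean(core**2)))
    if rms == 0.0:
        raise ValueError("cannot calibrate a silent waveform (zero RMS)")
    target = P_REF * 10.0 ** (level_db_spl / 20.0)
    samples = w.samples * (target / rms)
    if n_ramp:
        env = np.ones(n)
        # Raised cosine from 0 to 1 over the ramp; mirrored at offset.
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = r
        env[n - n_ramp :] = r[::-1]
        samples = samples * env
    return Waveform(samples, w.sample_rate)


def synthesize(
    spec: StimulusSpec, rng: np.random.Generator | None = None, **irn_kwargs
) -> Waveform:
    """Full synthesis: raw generator for the spec's kind, then calibration."""
    if spec.kind == "irn":
        raw = make_irn(spec, rng, **irn_kwargs)
    else:
        raw = make_harmonic_complex(spec)
    return calibrate(raw, spec.level_db_spl, spec.ramp)


def make_training_set(
    f0_lo: float,
    f0_hi: float,
    step: float,
    profile: float | str | None = "flat",
    *,
    kind: str = "harmonic",
    **spec_kwargs,
) -> list[StimulusSpec]:
    """Build a stimulus set on an inclusive arithmetic F0 grid.

    ``profile`` sets the harmonic decay: ``"flat"`` / ``None`` for constant
    amplitudes, or a positive number ``c`` meaning ``tau = c * F0`` (the
    decay constant scales with the fundamental, so the per-harmonic
    attenuation pattern is shared across the grid).
    """
    if f0_lo > f0_hi:
        raise ValueError("f0_lo must not exceed f0_hi")
    if step <= 0:
        raise ValueError("step must be positive")
    n = math.floor((f0_hi - f0_lo) / step + 1e-9) + 1
    f0s = [f0_lo + i * step for i in range(n)]
    if not f0s:
        raise ValueError("empty F0 grid")
    specs = []
    for f0 in f0s:
        if profile is None or profile == "flat":
            tau = None
        else:
            c = float(profile)
            if c <= 0:
                raise ValueError("profile multiplier must be positive")
            tau = c * f0
        specs.append(StimulusSpec(kind=kind, f0=f0, tau=tau, **spec_kwargs))
    return specs


def sample_random_tau(f0: float, rng: np.random.Generator) -> float:
    """Draw a decay constant tau = f0 * exp(x), x ~ Uniform[0, 10].

    The resulting tau/f0 ratios are log-uniform between 1 and e^10, so
    training sees many near-flat profiles and fewer sharply decaying ones.
    """
    if not f0 > 0:
        raise ValueError("f0 must be positive")
    return float(f0 * np.exp(rng.uniform(0.0, 10.0)))


def write_wav(w: Waveform, path: str | Path, *, subtype: str = "float32") -> None:
    """Write a mono waveform to a RIFF WAV file (float32 or PCM16)."""
    path = Path(path)
    if subtype == "float32":
        wavfile.write(path, round(w.sample_rate), w.samples.astype(np.float32))
    elif subtype == "pcm16":
        peak = float(np.max(np.abs(w.samples)))
        if peak > 1.0:
            raise ValueError("PCM16 export requires samples within [-1, 1]")
        wavfile.write(
            path, round(w.sample_rate), np.round(w.samples * 32767).astype(np.int16)
        )
    else:
        raise ValueError(f"unsupported WAV subtype {subtype!r}")


def read_wav(path: str | Path) -> Waveform:
    """Read a mono WAV file; integer containers are rescaled to [-1, 1]."""
    rate, data = wavfile.read(Path(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: only mono WAV files are supported")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483647.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported sample format {data.dtype}")
    return Waveform(samples, float(rate))


def specs_to_manifest(specs: Sequence[StimulusSpec], paths: Iterable[str] | None = None):
    """Tabulate a stimulus set as a manifest DataFrame (one row per sound)."""
    import pandas as pd

    rows = []
    paths = list(paths) if paths is not None else [""] * len(specs)
    for spec, p in zip(specs, paths):
        rows.append(
            dict(
                kind=spec.kind,
                f0=spec.f0,
                n_harmonics=spec.n_harmonics,
                tau="flat" if spec.tau is None else spec.tau,
                irn_iterations=spec.irn_iterations,
                level_db_spl=spec.level_db_spl,
                noise_seed=spec.noise_seed,
                path=p,
            )
        )
    return pd.DataFrame(rows)
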