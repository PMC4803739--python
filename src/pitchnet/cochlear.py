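"""Simplified auditory-nerve front-end.

Converts a calibrated waveform into a vector of time-averaged,
max-normalized auditory-nerve-fiber (ANF) firing rates on a logarithmic
characteristic-frequency (CF) grid — by default 2500 fibers from 125 Hz
to 20 kHz, mirroring the tonotopic map of the cochlea.

The built-in rate model is deliberately minimal: each channel applies the
magnitude response of a 4th-order gammatone filter centred at its CF
(bandwidth scaling with the equivalent rectangular bandwidth, ERB, of
Glasberg & Moore), half-wave rectifies the filtered signal, compresses it
with a power law (exponent 0.3 by default), averages over time, and
silences fibers driven below the absolute hearing threshold (0 dB SPL):
the mean compressed response a threshold-level tone would evoke is
subtracted and the rate clipped at zero.  Without this floor the power
law assigns substantial rates to channels tens of dB below the stimulus,
burying the tonotopic contrast the network learns from.  The filter is
applied zero-phase (magnitude only).  This reproduces the feature the
downstream network depends on — a tonotopic excitation pattern in which
low harmonics are resolved as separate peaks and high harmonics merge —
without any claim to detailed nerve biophysics.  Externally computed
rates (e.g. from a full phenomenological cochlear model) can be injected
through :func:`adapter_rates`.

Across-fiber normalization defaults to unit L2 length in the pipeline
(:func:`rates_for_spec`): it keeps the Hebbian update ``k * r_out * r_in``
commensurate with the unit-norm weight rows, so each presentation blends
into — rather than overwrites — a neuron's tuning.  Peak normalization
(max = 1) is available everywhere via ``normalization="max"`` and is the
default contract of :func:`normalize_rates` itself.

For strictly periodic tone complexes the steady-state response of the
zero-phase filter bank is itself periodic with the stimulus period, so
:func:`tone_complex_rates` evaluates the rectified, compressed average
exactly over a single fundamental period — orders of magnitude faster
than filtering the full waveform, and used throughout the training
pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import fft as sfft

from .stimuli import StimulusSpec, Waveform, harmonic_amplitudes, synthesize

__all__ = [
    "CFGrid",
    "ANFRateVector",
    "make_cf_grid",
    "erb",
    "gammatone_gain",
    "anf_rates",
    "tone_complex_rates",
    "rates_for_spec",
    "normalize_rates",
    "adapter_rates",
    "DEFAULT_COMPRESSION",
]

#: Default power-law compression exponent applied after rectification.
DEFAULT_COMPRESSION = 0.3

#: Across-fiber normalization used by the pipeline (see module docstring).
DEFAULT_NORMALIZATION = "l2"

#: Absolute hearing threshold, pascal (0 dB SPL re 20 uPa).
P_THRESHOLD = 20e-6

#: Gammatone filter order of the built-in model.
_ORDER = 4

#: Conventional gammatone bandwidth factor relating the -3 dB-equivalent
#: bandwidth parameter to the ERB (Patterson's 1.019).
_BW_FACTOR = 1.019


@dataclass(frozen=True)
class CFGrid:
    """Ordered characteristic frequencies of the fiber array, in Hz."""

    cfs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "cfs", np.asarray(self.cfs, dtype=np.float64))
        if self.cfs.ndim != 1 or self.cfs.size < 2:
            raise ValueError("CF grid needs at least two frequencies")
        if not np.all(np.diff(self.cfs) > 0):
            raise ValueError("CFs must be strictly increasing")

    @property
    def n(self) -> int:
        return self.cfs.size


@dataclass(frozen=True)
class ANFRateVector:
    """Normalized time-averaged firing rates, one per fiber."""

    rates: np.ndarray
    grid: CFGrid

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=np.float64))
        if self.rates.shape != (self.grid.n,):
            raise ValueError("rate vector length must match the CF grid")
        if np.any(self.rates < 0) or np.any(self.rates > 1 + 1e-12):
            raise ValueError("rates must lie in [0, 1]")


def make_cf_grid(n: int = 2500, lo: float = 125.0, hi: float = 20_000.0) -> CFGrid:
    """Log-spaced CF grid with exact endpoints."""
    if n < 2:
        raise ValueError("need at least two fibers")
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    return CFGrid(np.geomspace(lo, hi, n))


def erb(f: np.ndarray | float) -> np.ndarray | float:
    """Equivalent rectangular bandwidth (Hz) at frequency f (Hz)."""
    return 24.7 * (4.37 * np.asarray(f) / 1000.0 + 1.0)


def gammatone_gain(f: np.ndarray, cf: np.ndarray) -> np.ndarray:
    """Magnitude response of a 4th-order gammatone at CF, unit peak gain.

    ``f`` and ``cf`` broadcast; the response is
    ``[1 + ((f - cf)/b)^2]^(-order/2)`` with ``b = 1.019 * ERB(cf)``,
    the standard all-pole gammatone approximation.
    """
    b = _BW_FACTOR * erb(cf)
    return (1.0 + ((f - cf) / b) ** 2) ** (-_ORDER / 2.0)


def normalize_rates(raw: np.ndarray, grid: CFGrid, *, mode: str = "max") -> ANFRateVector:
    """Normalize a raw rate vector across fibers.

    ``mode="max"`` (default) divides by the maximum, giving values in
    [0, 1] with max exactly 1; ``mode="l2"`` rescales the vector to unit
    Euclidean length instead (entries still in [0, 1], max typically < 1).
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.shape != (grid.n,):
        raise ValueError("rate vector length must match the CF grid")
    if np.any(raw < 0):
        raise ValueError("raw rates must be non-negative")
    peak = raw.max()
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero rate vector")
    if mode == "max":
        return ANFRateVector(raw / peak, grid)
    if mode == "l2":
        return ANFRateVector(raw / np.linalg.norm(raw), grid)
    raise ValueError(f"unknown normalization mode {mode!r}")


def _rectify_compress_mean(y: np.ndarray, compression: float) -> np.ndarray:
    """Row-wise mean of relu(y)**compression without materialising powers
    of negative values."""
    pos = np.clip(y, 0.0, None)
    return np.mean(pos**compression, axis=-1)


def _threshold_rate(compression: float) -> float:
    """Mean compressed rectified response of a threshold-level (0 dB SPL)
    pure tone at its best channel; the firing floor subtracted from every
    channel's raw rate."""
    phase = 2.0 * np.pi * np.arange(4096) / 4096
    c0 = float(np.mean(np.clip(np.sin(phase), 0.0, None) ** compression))
    # threshold *amplitude*: RMS p_thr corresponds to amplitude sqrt(2)*p_thr
    return c0 * (np.sqrt(2.0) * P_THRESHOLD) ** compression


def _apply_floor(raw: np.ndarray, compression: float) -> np.ndarray:
    return np.clip(raw - _threshold_rate(compression), 0.0, None)


def anf_rates(
    w: Waveform,
    grid: CFGrid,
    *,
    compression: float = DEFAULT_COMPRESSION,
    normalization: str | None = DEFAULT_NORMALIZATION,
    chunk: int = 256,
) -> ANFRateVector | np.ndarray:
    """Built-in front-end for an arbitrary waveform.

    Filters the signal through the zero-phase gammatone bank channel by
    channel (frequency-domain multiplication, processed in chunks to
    bound memory), rectifies, compresses, averages over the full
    stimulus duration and applies the hearing-threshold floor.  Channels
    whose CF exceeds the Nyquist frequency are set to zero rate with a
    warning.  Silence (or an entirely sub-threshold input) returns an
    all-zero vector with a warning, normalization skipped.
    ``normalization=None`` returns the raw floored rates.
    """
    x = w.samples
    n = x.size
    nyq = w.sample_rate / 2.0
    if np.all(x == 0.0):
        warnings.warn("silent input: returning all-zero rate vector")
        zero = np.zeros(grid.n)
        return ANFRateVector(zero, grid) if normalization else zero
    spec = sfft.rfft(x)
    freqs = sfft.rfftfreq(n, d=1.0 / w.sample_rate)
    raw = np.zeros(grid.n)
    alive = grid.cfs < nyq
    if not np.all(alive):
        warnings.warn(
            f"{int((~alive).sum())} channels above Nyquist ({nyq:g} Hz) set to zero"
        )
    idx_alive = np.flatnonzero(alive)
    for start in range(0, idx_alive.size, chunk):
        idx = idx_alive[start : start + chunk]
        gains = gammatone_gain(freqs[None, :], grid.cfs[idx, None])
        y = sfft.irfft(spec[None, :] * gains, n=n, axis=-1)
        raw[idx] = _rectify_compress_mean(y, compression)
    raw = _apply_floor(raw, compression)
    if normalization is None:
        return raw
    if raw.max() <= 0:
        warnings.warn("entirely sub-threshold input: all-zero rate vector")
        return ANFRateVector(np.zeros(grid.n), grid)
    return normalize_rates(raw, grid, mode=normalization)


def tone_complex_rates(
    spec: StimulusSpec,
    grid: CFGrid,
    *,
    compression: float = DEFAULT_COMPRESSION,
    normalization: str | None = DEFAULT_NORMALIZATION,
    samples_per_period: int = 256,
) -> ANFRateVector | np.ndarray:
    """Exact steady-state front-end response to a periodic tone complex.

    The zero-phase filter bank maps the sine-phase complex
    ``sum_k a_k sin(2 pi k f0 t)`` to
    ``sum_k a_k |H(k f0)| sin(2 pi k f0 t)`` per channel, which is
    periodic with period ``1/f0``; the rectified compressed time average
    is therefore evaluated over one densely sampled period.  Onset and
    offset ramps are transient and excluded.  Matches :func:`anf_rates`
    on the same stimulus up to ramp/edge effects.
    """
    if spec.kind == "irn":
        raise ValueError("tone_complex_rates handles periodic tone complexes only")
    ks = np.asarray(spec.harmonic_numbers, dtype=float)
    freqs = ks * spec.f0
    nyq = spec.sample_rate / 2.0
    amps = harmonic_amplitudes(spec)
    # Calibration is a linear gain; with power-law compression it rescales
    # every channel equally and cancels under max-normalization, but we
    # apply it so un-normalized outputs are level-faithful.
    level_gain = _calibration_gain(amps, spec)
    alive = grid.cfs < nyq
    gains = gammatone_gain(freqs[None, :], grid.cfs[:, None])  # (n_ch, n_harm)
    weighted = gains * (level_gain * amps)[None, :]
    weighted[~alive, :] = 0.0
    m = samples_per_period
    phase = 2.0 * np.pi * np.outer(ks, np.arange(m) / m)  # (n_harm, m)
    y = weighted @ np.sin(phase)  # (n_ch, m)
    raw = _rectify_compress_mean(y, compression)
    raw[~alive] = 0.0
    raw = _apply_floor(raw, compression)
    if normalization is None:
        return raw
    return normalize_rates(raw, grid, mode=normalization)


def _calibration_gain(amps: np.ndarray, spec: StimulusSpec) -> float:
    """Gain applied by dB-SPL calibration to a sine-phase complex.

    Long-run RMS of ``sum_k a_k sin(...)`` with distinct harmonics is
    ``sqrt(sum a_k^2 / 2)``.
    """
    from .stimuli import P_REF

    rms = float(np.sqrt(np.sum(amps**2) / 2.0))
    target = P_REF * 10.0 ** (spec.level_db_spl / 20.0)
    return target / rms


def rates_for_spec(
    spec: StimulusSpec,
    grid: CFGrid,
    *,
    compression: float = DEFAULT_COMPRESSION,
    normalization: str = DEFAULT_NORMALIZATION,
    rng: np.random.Generator | None = None,
) -> ANFRateVector:
    """Front-end response for a stimulus spec.

    Tone complexes use the exact steady-state fast path; IRNs (and any
    future aperiodic stimuli) are synthesized and run through the generic
    waveform path.
    """
    if spec.kind == "irn":
        w = synthesize(spec, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # expected above-Nyquist notice
            return anf_rates(w, grid, compression=compression, normalization=normalization)
    return tone_complex_rates(
        spec, grid, compression=compression, normalization=normalization
    )


def adapter_rates(
    adapter: Callable[[Waveform, CFGrid], np.ndarray],
    w: Waveform,
    grid: CFGrid,
) -> ANFRateVector:
    """Run an external rate-model adapter and normalize its output.

    The adapter contract: given a calibrated waveform and the CF grid,
    return one non-negative, finite time-averaged rate per CF, in grid
    order.  Length mismatches and non-finite values are rejected with
    diagnostics.
    """
    raw = np.asarray(adapter(w, grid), dtype=np.float64)
    if raw.shape != (grid.n,):
        raise ValueError(
            f"adapter returned {raw.shape} rates, expected ({grid.n},)"
        )
    if not np.all(np.isfinite(raw)):
        bad = int(np.sum(~np.isfinite(raw)))
        raise ValueError(f"adapter returned {bad} non-finite rate(s)")
    return normalize_rates(raw, grid)
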