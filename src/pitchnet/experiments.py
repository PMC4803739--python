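"""Experiment designs: training regimes, response maps and pitch decoding.

The study design: train the competitive network on harmonic complexes
whose fundamentals span 200–600 Hz in 20 Hz steps (21 stimuli per epoch,
randomized order), then probe it — without learning — with F0-containing
complexes, missing-fundamental (MF) complexes and iterated rippled
noises, collecting a *response map* (stimuli ordered by F0 x output
cells, post-sigmoid rates).  Two regimes are provided:

* **fixed profile** — every training stimulus shares one harmonic decay
  profile (flat, or ``tau = c * F0``); 50 epochs;
* **random decay** — a fresh decay constant ``tau = F0 * exp(x)``,
  ``x ~ U[0, 10]``, is drawn for every stimulus on every epoch; 100
  epochs.  This exposes the network to profiles from sharply decaying to
  near-flat and is the regime that generalizes best to MF and IRN sounds.

Pitch decoding reads the map the way the sorted heatmaps are read by
eye: each output cell is labelled with the training F0 at which it fires
hardest, and a test sound is decoded as the label gathering the largest
summed rate among the cells it drives above the sigmoid midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cochlear import ANFRateVector, CFGrid, make_cf_grid, rates_for_spec
from .network import (
    NetworkParams,
    NetworkState,
    init_network,
    present,
    train,
)
from .stimuli import StimulusSpec, make_training_set, sample_random_tau

__all__ = [
    "ResponseMap",
    "PitchDecoding",
    "FixedProfileResult",
    "RandomDecayResult",
    "build_rate_vectors",
    "test_network",
    "sort_by_peak",
    "decode_pitch",
    "decoding_accuracy",
    "fit_network",
    "random_decay_epoch_rates",
    "default_irn_specs",
    "run_fixed_profile",
    "run_random_decay",
    "F0_LO",
    "F0_HI",
    "F0_STEP",
]

# Training F0 grid: 200-600 Hz in 20 Hz increments (21 fundamentals).
F0_LO, F0_HI, F0_STEP = 200.0, 600.0, 20.0


@dataclass(frozen=True)
class ResponseMap:
    """Post-sigmoid output rates, rows = test stimuli (ordered by F0)."""

    rates: np.ndarray  # (n_stimuli, n_out), entries in (0, 1)
    f0_labels: np.ndarray  # Hz per row
    stimulus_kind: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=np.float64))
        object.__setattr__(
            self, "f0_labels", np.asarray(self.f0_labels, dtype=np.float64)
        )
        if self.rates.ndim != 2:
            raise ValueError("response map must be 2-D")
        if self.rates.shape[0] != self.f0_labels.size:
            raise ValueError("one F0 label per stimulus row required")

    @property
    def n_stimuli(self) -> int:
        return self.rates.shape[0]

    @property
    def n_cells(self) -> int:
        return self.rates.shape[1]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.rates,
            index=pd.Index(self.f0_labels, name="f0_hz"),
            columns=[f"cell_{i}" for i in range(self.n_cells)],
        )
        df.insert(0, "kind", list(self.stimulus_kind))
        return df


@dataclass(frozen=True)
class PitchDecoding:
    """Decoded pitch per test stimulus plus per-cell preferred F0s."""

    f0_true: np.ndarray
    f0_decoded: np.ndarray  # NaN where no cell was active
    confidence: np.ndarray  # summed rate of the winning label's active cells
    cell_labels: np.ndarray  # preferred training F0 per cell

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            dict(
                f0_true=self.f0_true,
                f0_decoded=self.f0_decoded,
                confidence=self.confidence,
            )
        )


def build_rate_vectors(
    specs: Sequence[StimulusSpec],
    grid: CFGrid,
    rng: np.random.Generator | None = None,
) -> list[ANFRateVector]:
    """Front-end rate vectors for a list of stimulus specs."""
    return [rates_for_spec(s, grid, rng=rng) for s in specs]


def test_network(
    state: NetworkState,
    inputs: Sequence[ANFRateVector],
    params: NetworkParams,
    f0_labels: Sequence[float],
    kinds: Sequence[str],
) -> ResponseMap:
    """Probe the network with a test set; weights are never modified."""
    rows = [present(state, x, params).output_rates for x in inputs]
    return ResponseMap(np.vstack(rows), np.asarray(f0_labels), tuple(kinds))


def sort_by_peak(resp: ResponseMap) -> np.ndarray:
    """Permutation ordering cells by the stimulus index of their peak rate.

    Ties are broken by cell index (stable sort), matching how the sorted
    response heatmaps are laid out.
    """
    peak_row = np.argmax(resp.rates, axis=0)
    return np.argsort(peak_row, kind="stable")


def decode_pitch(train_map: ResponseMap, test_map: ResponseMap) -> PitchDecoding:
    """Label-vote pitch decoder.

    Each cell's label is the training F0 at which it fires maximally
    (ties -> lower F0 via argmax of the F0-ordered map).  For each test
    stimulus, cells with rate >= 0.5 vote for their label with their
    rate; the label with the largest summed active rate wins.  Ties are
    broken by the larger summed rate over *all* cells of the label, then
    by the lower F0.  A stimulus driving no cell above 0.5 decodes to NaN.
    """
    if train_map.n_cells != test_map.n_cells:
        raise ValueError("train and test maps must share the cell axis")
    cell_labels = train_map.f0_labels[np.argmax(train_map.rates, axis=0)]
    label_values = np.unique(cell_labels)
    # (n_labels, n_cells) membership matrix
    member = cell_labels[None, :] == label_values[:, None]
    decoded = np.full(test_map.n_stimuli, np.nan)
    confidence = np.zeros(test_map.n_stimuli)
    for i in range(test_map.n_stimuli):
        r = test_map.rates[i]
        active = r >= 0.5
        if not np.any(active):
            continue
        active_votes = member @ (r * active)
        total_votes = member @ r
        # lexicographic: active vote, then total vote, then lower F0
        order = np.lexsort((label_values, -total_votes, -active_votes))
        best = order[0]
        decoded[i] = label_values[best]
        confidence[i] = active_votes[best]
    return PitchDecoding(
        f0_true=test_map.f0_labels.copy(),
        f0_decoded=decoded,
        confidence=confidence,
        cell_labels=cell_labels,
    )


def decoding_accuracy(
    dec: PitchDecoding,
    *,
    tolerance_hz: float = F0_STEP,
    f0_min: float | None = None,
    f0_max: float | None = None,
) -> float:
    """Fraction of stimuli decoded within ``tolerance_hz`` of the true F0.

    Undetermined stimuli count as errors.  Optional F0 bounds restrict
    the evaluation to a sub-range of the grid (inclusive).
    """
    mask = np.ones(dec.f0_true.size, dtype=bool)
    if f0_min is not None:
        mask &= dec.f0_true >= f0_min
    if f0_max is not None:
        mask &= dec.f0_true <= f0_max
    if not np.any(mask):
        raise ValueError("no stimuli in the requested F0 range")
    err = np.abs(dec.f0_decoded[mask] - dec.f0_true[mask])
    hits = np.where(np.isnan(err), False, err <= tolerance_hz + 1e-9)
    return float(np.mean(hits))


def fit_network(
    inputs: Sequence[ANFRateVector],
    params: NetworkParams,
    init_rng: np.random.Generator,
    shuffle_rng: np.random.Generator,
    *,
    epochs: int | None = None,
) -> tuple[NetworkState, np.ndarray]:
    """Initialize and train; returns state plus per-epoch mean |dW|.

    The weight-change trajectory (mean absolute weight change per epoch)
    is the convergence diagnostic logged by the training runs.
    """
    state = init_network(params, init_rng)
    n_epochs = params.epochs if epochs is None else epochs
    changes = np.zeros(n_epochs)
    for e in range(n_epochs):
        before = state.W.copy()
        train(state, inputs, params, shuffle_rng, epochs=1)
        changes[e] = float(np.mean(np.abs(state.W - before)))
    return state, changes


@dataclass(frozen=True)
class FixedProfileResult:
    state: NetworkState
    f0_map: ResponseMap
    mf_map: ResponseMap
    weight_change: np.ndarray
    params: NetworkParams
    f0s: np.ndarray


def run_fixed_profile(
    profile: float | str | None,
    params: NetworkParams = NetworkParams(),
    *,
    seed: int = 0,
    grid: CFGrid | None = None,
    epochs: int | None = None,
    **stim_kwargs,
) -> FixedProfileResult:
    """Train on one harmonic decay profile, test on F0 and MF sets.

    ``profile`` is ``"flat"`` or a multiplier ``c`` (``tau = c * F0``).
    Training uses the 21-fundamental grid for ``params.epochs`` epochs
    (override with ``epochs``, e.g. 0 for an untrained baseline); both
    test sets share the training profile.
    """
    grid = grid if grid is not None else make_cf_grid(params.n_in)
    init_rng, shuffle_rng = _streams(seed, 2)
    train_specs = make_training_set(
        F0_LO, F0_HI, F0_STEP, profile, kind="harmonic", **stim_kwargs
    )
    mf_specs = make_training_set(
        F0_LO, F0_HI, F0_STEP, profile, kind="missing_fundamental", **stim_kwargs
    )
    train_rates = build_rate_vectors(train_specs, grid)
    mf_rates = build_rate_vectors(mf_specs, grid)
    state, changes = fit_network(
        train_rates, params, init_rng, shuffle_rng, epochs=epochs
    )
    f0s = np.array([s.f0 for s in train_specs])
    f0_map = test_network(state, train_rates, params, f0s, ["harmonic"] * len(f0s))
    mf_map = test_network(
        state, mf_rates, params, f0s, ["missing_fundamental"] * len(f0s)
    )
    return FixedProfileResult(state, f0_map, mf_map, changes, params, f0s)


def random_decay_epoch_rates(
    f0s: Sequence[float],
    grid: CFGrid,
    tau_rng: np.random.Generator,
    **stim_kwargs,
) -> list[ANFRateVector]:
    """One epoch's training vectors with freshly drawn decay constants."""
    out = []
    for f0 in f0s:
        tau = sample_random_tau(f0, tau_rng)
        spec = StimulusSpec(kind="harmonic", f0=f0, tau=tau, **stim_kwargs)
        out.append(rates_for_spec(spec, grid))
    return out


def default_irn_specs(
    f0s: Sequence[float], *, noise_seed_base: int = 9000, **stim_kwargs
) -> list[StimulusSpec]:
    """The IRN test set: 30 delay-and-add iterations, one noise seed per F0."""
    return [
        StimulusSpec(
            kind="irn", f0=f0, noise_seed=noise_seed_base + i, **stim_kwargs
        )
        for i, f0 in enumerate(f0s)
    ]


@dataclass(frozen=True)
class RandomDecayResult:
    state: NetworkState
    maps: dict[str, ResponseMap]  # keys: f0_tau_f0, mf_tau_f0, f0_flat, mf_flat, irn
    weight_change: np.ndarray
    params: NetworkParams
    f0s: np.ndarray


def run_random_decay(
    params: NetworkParams = NetworkParams(epochs=100),
    *,
    seed: int = 0,
    grid: CFGrid | None = None,
    include_irn: bool = True,
    epochs: int | None = None,
    **stim_kwargs,
) -> RandomDecayResult:
    """Random-decay training regime with the full test battery.

    Every epoch draws a fresh ``tau = F0 * exp(U[0, 10])`` for each of
    the 21 fundamentals, so no stimulus repeats across training.  After
    ``params.epochs`` (default 100) epochs the network is probed with
    the four complex-tone test sets (tau = F0 and flat, F0-containing
    and MF) and, optionally, the IRN set.
    """
    grid = grid if grid is not None else make_cf_grid(params.n_in)
    init_rng, shuffle_rng, tau_rng = _streams(seed, 3)
    f0s = np.arange(F0_LO, F0_HI + F0_STEP / 2, F0_STEP)
    state = init_network(params, init_rng)
    n_epochs = params.epochs if epochs is None else epochs
    changes = np.zeros(n_epochs)
    for e in range(n_epochs):
        rates = random_decay_epoch_rates(f0s, grid, tau_rng, **stim_kwargs)
        before = state.W.copy()
        train(state, rates, params, shuffle_rng, epochs=1)
        changes[e] = float(np.mean(np.abs(state.W - before)))
    maps = build_test_battery(
        state, params, grid, f0s, include_irn=include_irn, **stim_kwargs
    )
    return RandomDecayResult(state, maps, changes, params, f0s)


def build_test_battery(
    state: NetworkState,
    params: NetworkParams,
    grid: CFGrid,
    f0s: np.ndarray,
    *,
    include_irn: bool = True,
    irn_rates: Sequence[ANFRateVector] | None = None,
    **stim_kwargs,
) -> dict[str, ResponseMap]:
    """The standard post-training probe: four tone-complex maps (+ IRN)."""
    maps: dict[str, ResponseMap] = {}
    for key, profile, kind in [
        ("f0_tau_f0", 1.0, "harmonic"),
        ("mf_tau_f0", 1.0, "missing_fundamental"),
        ("f0_flat", "flat", "harmonic"),
        ("mf_flat", "flat", "missing_fundamental"),
    ]:
        specs = make_training_set(
            f0s[0], f0s[-1], float(f0s[1] - f0s[0]), profile, kind=kind, **stim_kwargs
        )
        vecs = build_rate_vectors(specs, grid)
        maps[key] = test_network(state, vecs, params, f0s, [kind] * len(f0s))
    if include_irn:
        if irn_rates is None:
            irn_specs = default_irn_specs(f0s, **stim_kwargs)
            irn_rates = build_rate_vectors(irn_specs, grid)
        maps["irn"] = test_network(state, irn_rates, params, f0s, ["irn"] * len(f0s))
    return maps


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
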