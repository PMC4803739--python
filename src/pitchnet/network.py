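"""One-layer competitive Hebbian network.

The model is a single layer of modifiable feedforward synapses from
``n_in`` rate-coded input cells (the auditory-nerve array) onto ``n_out``
output cells.  One stimulus presentation consists of:

1. activation: ``h_i = sum_j w_ij r_j`` (a plain weighted sum);
2. competition: a shared sigmoid threshold ``alpha`` is set to the
   ``m``-th highest activation, ``m = round(sparseness * n_out)``, so a
   fixed fraction of output cells ends up above the sigmoid midpoint —
   a soft winner-set implementation of lateral inhibition;
3. output rates: ``r_i = 1 / (1 + exp(-2 beta (h_i - alpha)))``;
4. (during learning) Hebbian update ``dw_ij = k r_i r_j`` followed by
   rescaling every output cell's weight vector to unit L2 norm, which
   prevents a few early winners from capturing all inputs.

All output cells learn with their post-sigmoid rates — losers contribute
their small but nonzero rates; there is no hard winner-take-all mask.
Weight initialisation and epoch shuffling use separate RNG streams so the
initial-weight seed can be varied while holding the presentation order
fixed, and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .cochlear import ANFRateVector

__all__ = [
    "NetworkParams",
    "NetworkState",
    "LayerActivity",
    "init_network",
    "compute_activations",
    "compute_threshold",
    "winner_count",
    "apply_sigmoid",
    "hebbian_update",
    "present",
    "train",
]

#: Clamp on the sigmoid exponent argument; purely a floating-point
#: overflow guard, non-semantic (saturated rates are 0/1 either way).
_EXP_CLAMP = 700.0

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class NetworkParams:
    """Fixed parameters of the competitive network.

    Defaults are the simulation constants used throughout: 2500 inputs,
    200 outputs, learning rate ``k = 0.25``, sigmoid slope
    ``beta = 17.45``, sparseness 10 % and 50 training epochs.
    """

    n_in: int = 2500
    n_out: int = 200
    learning_rate: float = 0.25
    slope: float = 17.45
    sparseness: float = 0.10
    epochs: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_in < 1 or self.n_out < 1:
            raise ValueError("layer sizes must be >= 1")
        if self.learning_rate <= 0 or self.slope <= 0:
            raise ValueError("learning_rate and slope must be positive")
        if not (0 < self.sparseness <= 1):
            raise ValueError("sparseness must lie in (0, 1]")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if round(self.sparseness * self.n_out) < 1:
            raise ValueError("sparseness * n_out must round to >= 1 winner")


@dataclass
class NetworkState:
    """Synaptic weight matrix, n_out rows x n_in columns, unit-L2 rows."""

    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.ndim != 2:
            raise ValueError("W must be a 2-D matrix")

    @property
    def n_out(self) -> int:
        return self.W.shape[0]

    @property
    def n_in(self) -> int:
        return self.W.shape[1]

    def row_norms(self) -> np.ndarray:
        return np.linalg.norm(self.W, axis=1)

    def copy(self) -> "NetworkState":
        return NetworkState(self.W.copy())


@dataclass(frozen=True)
class LayerActivity:
    """Record of a single stimulus presentation (no learning)."""

    input_rates: np.ndarray
    activations: np.ndarray
    threshold: float
    output_rates: np.ndarray
    #: number of cells with activation >= threshold; exceeds the target
    #: winner count only when activations tie exactly at the threshold
    n_above: int
    #: intended winner count m = round(sparseness * n_out)
    n_target: int

    @property
    def tied_at_threshold(self) -> bool:
        return self.n_above != self.n_target


def init_network(
    params: NetworkParams, rng: np.random.Generator | None = None
) -> NetworkState:
    """Random initial weights: uniform(0,1) entries, rows L2-normalized."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    W = rng.uniform(0.0, 1.0, size=(params.n_out, params.n_in))
    W /= np.linalg.norm(W, axis=1, keepdims=True)
    return NetworkState(W)


def _as_rates(input_rates) -> np.ndarray:
    if isinstance(input_rates, ANFRateVector):
        return input_rates.rates
    return np.asarray(input_rates, dtype=np.float64)


def compute_activations(state: NetworkState, input_rates) -> np.ndarray:
    """Feedforward activations h = W r."""
    r = _as_rates(input_rates)
    if r.shape != (state.n_in,):
        raise ValueError(
            f"input length {r.shape} does not match n_in={state.n_in}"
        )
    return state.W @ r


def winner_count(n_out: int, sparseness: float) -> int:
    """Target winner-set size m = round(sparseness * n_out), at least 1."""
    m = round(sparseness * n_out)
    if m < 1:
        raise ValueError("sparseness * n_out must round to >= 1")
    return m


def compute_threshold(activations: np.ndarray, sparseness: float) -> float:
    """Shared sigmoid threshold: the m-th highest activation.

    Recomputed on every presentation; with the default 200 outputs and
    10 % sparseness this is the 20th highest activation, so exactly 20
    cells sit at or above threshold whenever activations are distinct.
    """
    h = np.asarray(activations, dtype=np.float64)
    m = winner_count(h.size, sparseness)
    return float(np.partition(h, h.size - m)[h.size - m])


def apply_sigmoid(
    activations: np.ndarray, alpha: float, beta: float
) -> np.ndarray:
    """Logistic output rates with gain 2*beta centred at alpha."""
    z = np.clip(-2.0 * beta * (np.asarray(activations) - alpha), -_EXP_CLAMP, _EXP_CLAMP)
    return 1.0 / (1.0 + np.exp(z))


def hebbian_update(
    state: NetworkState,
    output_rates: np.ndarray,
    input_rates,
    learning_rate: float,
) -> None:
    """In-place Hebbian update dW = k * outer(r_out, r_in), then re-unit rows."""
    r_in = _as_rates(input_rates)
    r_out = np.asarray(output_rates, dtype=np.float64)
    if r_in.shape != (state.n_in,) or r_out.shape != (state.n_out,):
        raise ValueError("rate vector dimensions do not match the network")
    state.W += learning_rate * np.outer(r_out, r_in)
    norms = np.linalg.norm(state.W, axis=1, keepdims=True)
    # Non-negative init plus non-negative updates keep rows nonzero.
    assert np.all(norms > 0), "weight row collapsed to zero"
    state.W /= norms


def present(state: NetworkState, input_rates, params: NetworkParams) -> LayerActivity:
    """One feedforward pass with competition; does not modify weights."""
    r = _as_rates(input_rates)
    h = compute_activations(state, r)
    alpha = compute_threshold(h, params.sparseness)
    rates = apply_sigmoid(h, alpha, params.slope)
    return LayerActivity(
        input_rates=r,
        activations=h,
        threshold=alpha,
        output_rates=rates,
        n_above=int(np.sum(h >= alpha)),
        n_target=winner_count(state.n_out, params.sparseness),
    )


def train(
    state: NetworkState,
    inputs: Sequence,
    params: NetworkParams,
    shuffle_rng: np.random.Generator | None = None,
    *,
    epochs: int | None = None,
    on_update: Callable[[NetworkState, int, int], None] | None = None,
) -> NetworkState:
    """Train in place for ``epochs`` epochs (default ``params.epochs``).

    Each epoch presents every input once in a fresh random order (a plain
    permutation drawn from ``shuffle_rng``), applying the Hebbian update
    online after each presentation.  ``on_update(state, epoch, step)`` is
    invoked after every weight update, e.g. to audit row norms or log
    weight-change trajectories.  Returns ``state`` for chaining.
    """
    if len(inputs) == 0:
        raise ValueError("training set is empty")
    if shuffle_rng is None:
        shuffle_rng = np.random.default_rng(
            None if params.seed is None else params.seed + 1
        )
    n_epochs = params.epochs if epochs is None else epochs
    mats = [_as_rates(x) for x in inputs]
    for epoch in range(n_epochs):
        order = shuffle_rng.permutation(len(mats))
        for step, idx in enumerate(order):
            act = present(state, mats[idx], params)
            hebbian_update(state, act.output_rates, mats[idx], params.learning_rate)
            if on_update is not None:
                on_update(state, epoch, step)
    return state
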