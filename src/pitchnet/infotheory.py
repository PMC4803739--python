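"""Single-cell stimulus-specific information analysis.

Output-cell responses to a stimulus set are binarized at a firing-rate
cutoff (0.5 by default: a cell is "active" when its post-sigmoid rate
exceeds the sigmoid midpoint) and each cell's response is scored with
the stimulus-specific information

    I(s, R) = sum_{r in R} P(r|s) log2( P(r|s) / P(r) )   [bits]

under a uniform prior over the presented stimuli.  Because the network is
deterministic, each cell gives exactly one binary response per stimulus,
so P(r|s) is degenerate (0 or 1) and P(r) is the fraction of stimuli for
which the cell is in state r.  The information any single cell can carry
is bounded by I_max = log2(N) for N stimuli, attained exactly by a cell
active for one stimulus and silent for the rest (or vice versa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BinaryResponseTable",
    "InfoResult",
    "binarize",
    "stimulus_specific_info",
    "max_info",
    "summarize",
]


@dataclass(frozen=True)
class BinaryResponseTable:
    """Boolean table, rows = stimuli, columns = cells; True = active."""

    states: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", np.asarray(self.states, dtype=bool))
        if self.states.ndim != 2:
            raise ValueError("response table must be 2-D (stimuli x cells)")

    @property
    def n_stimuli(self) -> int:
        return self.states.shape[0]

    @property
    def n_cells(self) -> int:
        return self.states.shape[1]


@dataclass(frozen=True)
class InfoResult:
    """Per-(stimulus, cell) information in bits, plus the log2(N) bound."""

    info: np.ndarray  # (n_stimuli, n_cells), bits
    i_max: float


def binarize(rates: np.ndarray, threshold: float = 0.5) -> BinaryResponseTable:
    """Binarize a response map: active iff rate strictly exceeds threshold.

    A rate of exactly ``threshold`` is a cell sitting precisely at the
    competition threshold and is classed inactive.
    """
    rates = np.asarray(getattr(rates, "rates", rates), dtype=np.float64)
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    return BinaryResponseTable(rates > threshold, threshold)


def max_info(n_stimuli: int) -> float:
    """Upper bound log2(N) on single-cell information, in bits."""
    if n_stimuli < 1:
        raise ValueError("need at least one stimulus")
    return float(np.log2(n_stimuli))


def stimulus_specific_info(table: BinaryResponseTable) -> InfoResult:
    """Stimulus-specific information of every cell for every stimulus.

    With deterministic binary responses and a uniform stimulus prior the
    sum collapses to a single term: I(s, R) = -log2 P(r_s), where r_s is
    the cell's observed state for stimulus s and P(r_s) its marginal
    frequency across stimuli.  Terms with P(r|s) = 0 contribute nothing
    (0 log 0 := 0).
    """
    if table.n_stimuli < 2:
        raise ValueError("need at least two stimuli for an informative prior")
    if table.n_cells < 1:
        raise ValueError("need at least one cell")
    s = table.states
    p_active = s.mean(axis=0)  # P(active) per cell under the uniform prior
    # marginal probability of each observed state
    p_observed = np.where(s, p_active[None, :], 1.0 - p_active[None, :])
    # p_observed >= 1/N > 0 because the state was observed at least once
    info = -np.log2(p_observed)
    return InfoResult(info=info, i_max=max_info(table.n_stimuli))


def summarize(
    result: InfoResult, *, cell_statistic: str = "max"
) -> tuple[np.ndarray, np.ndarray]:
    """Ranked per-cell curve and per-stimulus maximum profile.

    Per cell, the scalar summary is the max (default) or mean over
    stimuli of I(s, R); cells are sorted descending to give the ranked
    single-cell information curve.  Per stimulus, the profile is the max
    over cells — how well the best cell signals that stimulus.
    """
    if result.info.size == 0:
        raise ValueError("empty information matrix")
    if cell_statistic == "max":
        per_cell = result.info.max(axis=0)
    elif cell_statistic == "mean":
        per_cell = result.info.mean(axis=0)
    else:
        raise ValueError(f"unknown cell_statistic {cell_statistic!r}")
    ranked = np.sort(per_cell)[::-1]
    per_stimulus_max = result.info.max(axis=1)
    return ranked, per_stimulus_max
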