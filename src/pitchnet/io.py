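"""Plain-text exchange formats and model persistence.

Rate vectors and CF grids travel as CSV (one value per fiber, ordered by
the grid); response maps as CSV with an ``f0_hz`` index and a ``kind``
column; trained networks as a flat ``.npy`` weight array plus a JSON
sidecar recording dimensions and parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cochlear import ANFRateVector, CFGrid
from .experiments import ResponseMap
from .network import NetworkParams, NetworkState

__all__ = [
    "save_cf_grid",
    "load_cf_grid",
    "save_rates",
    "load_rates",
    "save_response_map",
    "load_response_map",
    "save_network",
    "load_network",
]


def save_cf_grid(grid: CFGrid, path: str | Path) -> None:
    pd.DataFrame({"index": np.arange(grid.n), "cf_hz": grid.cfs}).to_csv(
        path, index=False
    )


def load_cf_grid(path: str | Path) -> CFGrid:
    df = pd.read_csv(path)
    return CFGrid(df["cf_hz"].to_numpy())


def save_rates(vec: ANFRateVector, path: str | Path) -> None:
    pd.DataFrame({"cf_hz": vec.grid.cfs, "rate": vec.rates}).to_csv(
        path, index=False
    )


def load_rates(path: str | Path, grid: CFGrid | None = None) -> ANFRateVector:
    df = pd.read_csv(path)
    g = grid if grid is not None else CFGrid(df["cf_hz"].to_numpy())
    return ANFRateVector(df["rate"].to_numpy(), g)


def save_response_map(resp: ResponseMap, path: str | Path) -> None:
    resp.to_frame().to_csv(path)


def load_response_map(path: str | Path) -> ResponseMap:
    df = pd.read_csv(path, index_col="f0_hz")
    kinds = tuple(df.pop("kind"))
    return ResponseMap(df.to_numpy(), df.index.to_numpy(), kinds)


def save_network(
    state: NetworkState, params: NetworkParams, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "weights.npy", state.W)
    meta = asdict(params) | {"n_out": state.n_out, "n_in": state.n_in}
    (out / "network.json").write_text(json.dumps(meta, indent=2))


def load_network(model_dir: str | Path) -> tuple[NetworkState, NetworkParams]:
    model_dir = Path(model_dir)
    W = np.load(model_dir / "weights.npy")
    meta = json.loads((model_dir / "network.json").read_text())
    params = NetworkParams(
        **{k: meta[k] for k in (
            "n_in", "n_out", "learning_rate", "slope", "sparseness", "epochs", "seed"
        )}
    )
    return NetworkState(W), params
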