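"""File formats: HDF5 trial tensors, CSV edge lists, TE matrices, sessions."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import TrialTensor
from .te import TEMatrix

__all__ = [
    "write_tensor", "read_tensor", "write_te_matrix", "read_te_matrix",
    "write_edge_list", "read_edge_list",
]


def write_tensor(path, tensor: TrialTensor) -> None:
    """HDF5 container with datasets mua, time_ms, trial_ids."""
    with h5py.File(path, "w") as f:
        f.create_dataset("mua", data=tensor.mua)
        f.create_dataset("time_ms", data=tensor.time_ms)
        f.create_dataset("trial_ids", data=np.asarray(tensor.trial_ids))
        f.attrs["dt_ms"] = tensor.dt_ms
        f.attrs["condition"] = tensor.condition
        f.attrs["alignment"] = tensor.alignment


def read_tensor(path) -> TrialTensor:
    with h5py.File(path, "r") as f:
        return TrialTensor(
            mua=f["mua"][()], time_ms=f["time_ms"][()],
            trial_ids=f["trial_ids"][()], dt_ms=float(f.attrs["dt_ms"]),
            condition=str(f.attrs.get("condition", "")),
            alignment=str(f.attrs.get("alignment", "")),
        )


def write_te_matrix(path, m: TEMatrix) -> None:
    """Dense CSV plus a JSON metadata sidecar (and an edge-list CSV)."""
    path = Path(path)
    pd.DataFrame(m.values).to_csv(path, index=False)
    src, dst = np.nonzero(m.values > 0)
    pd.DataFrame({
        "source": src, "target": dst, "te_nats": m.values[src, dst],
    }).to_csv(path.with_suffix(".edges.csv"), index=False)
    meta = {"condition": m.condition, "session": m.session,
            "trial_averaged": m.trial_averaged, "n_nodes": m.n_nodes}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, sort_keys=True))


def read_te_matrix(path) -> TEMatrix:
    path = Path(path)
    values = pd.read_csv(path).to_numpy(dtype=float)
    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return TEMatrix(values=values, condition=meta.get("condition", ""),
                    session=meta.get("session", ""),
                    trial_averaged=meta.get("trial_averaged", False))


def write_edge_list(path, truth) -> None:
    truth.to_frame().to_csv(path, index=False)


def read_edge_list(path):
    from .synthetic import Edge, GroundTruthNetwork

    df = pd.read_csv(path)
    edges = [
        Edge(int(r.source), int(r.target), int(r.lag_ms), float(r.strength),
             frozenset(str(r.conditions).split("|")))
        for r in df.itertuples()
    ]
    n_nodes = int(max((max(e.source, e.target) for e in edges), default=-1)) + 1
    return GroundTruthNetwork(n_nodes=n_nodes, edges=edges)
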