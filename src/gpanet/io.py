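"""Persistence: HDF5 trajectory container and CSV exports.

Layout of the HDF5 container:

    /params      gamma, beta, activation (attrs)
    /coupling    J, g
    /trajectory  x, a, (u); attrs t0, dt
    attrs        metadata (JSON string)
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .network import CouplingMatrix, NetworkModel, NeuronPopulation

__all__ = ["save_trajectory", "load_trajectory", "load_model", "export_neurons_csv"]


def save_trajectory(path, traj: Trajectory, model: NetworkModel | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("trajectory")
        g.create_dataset("x", data=traj.x, compression="gzip")
        g.create_dataset("a", data=traj.a, compression="gzip")
        if traj.u is not None:
            g.create_dataset("u", data=traj.u, compression="gzip")
        g.attrs["t0"] = traj.t0
        g.attrs["dt"] = traj.dt
        f.attrs["metadata"] = json.dumps(traj.model_ref)
        if model is not None:
            p = f.create_group("params")
            p.create_dataset("gamma", data=model.population.gamma)
            p.create_dataset("beta", data=model.population.beta)
            p.attrs["activation"] = model.population.activation
            c = f.create_group("coupling")
            c.create_dataset("J", data=model.coupling.J, compression="gzip")
            c.attrs["g"] = model.coupling.g


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        g = f["trajectory"]
        return Trajectory(
            t0=float(g.attrs["t0"]),
            dt=float(g.attrs["dt"]),
            x=g["x"][...],
            a=g["a"][...],
            u=g["u"][...] if "u" in g else None,
            model_ref=json.loads(f.attrs.get("metadata", "{}")),
        )


def load_model(path) -> NetworkModel:
    with h5py.File(path, "r") as f:
        if "params" not in f:
            raise KeyError(f"{path} stores no model group")
        pop = NeuronPopulation(
            gamma=f["params/gamma"][...],
            beta=f["params/beta"][...],
            activation=str(f["params"].attrs["activation"]),
        )
        coup = CouplingMatrix(J=f["coupling/J"][...], g=float(f["coupling"].attrs["g"]))
        meta = json.loads(f.attrs.get("metadata", "{}"))
    return NetworkModel(population=pop, coupling=coup, metadata=meta)


def export_neurons_csv(path, traj: Trajectory, neurons) -> None:
    """CSV of time plus x (and a) for the selected neuron indices."""
    neurons = list(np.asarray(neurons, dtype=int))
    df = pd.DataFrame({"t": traj.times})
    for i in neurons:
        df[f"x_{i}"] = traj.x[:, i]
        df[f"a_{i}"] = traj.a[:, i]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
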