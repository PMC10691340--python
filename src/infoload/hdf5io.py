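"""HDF5 serialization of networks, mode sets and fitted models."""

from __future__ import annotations

import numpy as np
import h5py

from infoload.attractor import AttractorNet
from infoload.errors import FormatError
from infoload.lds import LDSFit
from infoload.linear import LinearNetwork, ModeSet

__all__ = [
    "save_linear_network", "load_linear_network", "save_modes", "load_modes",
    "save_attractor_net", "load_attractor_net", "save_lds_fit", "load_lds_fit",
    "save_overlap_curves", "save_decoding_matrix",
]


def save_overlap_curves(path, curves) -> None:
    """HDF5 mirror of an OverlapCurves object (CSV via curves.to_csv)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=curves.time)
        f.create_dataset("amplifying_pct", data=curves.amplifying_pct)
        f.create_dataset("persistent_pct", data=curves.persistent_pct)
        f.attrs["chance_median"] = curves.chance_median
        f.attrs["chance_lo"] = curves.chance_ci95[0]
        f.attrs["chance_hi"] = curves.chance_ci95[1]
        f.attrs["top_frac"] = curves.top_frac
        f.attrs["subspace_dims"] = list(curves.subspace_dims)


def save_decoding_matrix(path, mat) -> None:
    """Write a cross-temporal DecodingMatrix (/accuracy, /time)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("accuracy", data=mat.accuracy)
        f.create_dataset("time", data=mat.time)
        f.attrs["cv_folds"] = mat.cv_folds
        f.attrs["chance"] = mat.chance


def save_linear_network(path, net: LinearNetwork, modes: ModeSet | None = None,
                        provenance: dict | None = None) -> None:
    """Write /W, /A (+ optional /modes/*) with tau, sigma, kind attrs."""
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=net.weights)
        f.create_dataset("A", data=net.A)
        if net.persistent_vector is not None:
            f.create_dataset("persistent_vector", data=net.persistent_vector)
        f.attrs["tau"] = net.tau
        f.attrs["sigma"] = net.noise_sigma
        f.attrs["kind"] = net.kind
        for key, val in (provenance or {}).items():
            f.attrs[f"prov_{key}"] = val
        if modes is not None:
            _write_modes(f.create_group("modes"), modes)


def _write_modes(g, modes: ModeSet) -> None:
    g.create_dataset("directions", data=modes.directions)
    g.create_dataset("values", data=modes.values)
    g.create_dataset("basis", data=modes.basis)
    g.attrs["kind"] = modes.kind
    if modes.horizon is not None:
        g.attrs["horizon"] = modes.horizon


def load_linear_network(path) -> LinearNetwork:
    with h5py.File(path, "r") as f:
        if "W" not in f:
            raise FormatError(f"missing dataset /W in {path}")
        pv = f["persistent_vector"][()] if "persistent_vector" in f else None
        return LinearNetwork(f["W"][()], tau=float(f.attrs["tau"]),
                             noise_sigma=float(f.attrs["sigma"]),
                             kind=str(f.attrs["kind"]), persistent_vector=pv)


def save_modes(path, modes: ModeSet) -> None:
    with h5py.File(path, "w") as f:
        _write_modes(f, modes)


def load_modes(path) -> ModeSet:
    with h5py.File(path, "r") as f:
        if "directions" not in f:
            raise FormatError(f"missing dataset /directions in {path}")
        return ModeSet(kind=str(f.attrs["kind"]), directions=f["directions"][()],
                       values=f["values"][()], basis=f["basis"][()],
                       horizon=float(f.attrs["horizon"]) if "horizon" in f.attrs else None)


def save_attractor_net(path, net: AttractorNet, provenance: dict | None = None) -> None:
    """Write /W, /b, /X0, /readout with nonlinearity, tau, sigma attrs."""
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=net.weights)
        f.create_dataset("b", data=net.bias)
        f.create_dataset("X0", data=net.init_states)
        f.create_dataset("readout", data=net.readout_weights)
        f.create_dataset("readout_bias", data=net.readout_bias)
        f.attrs["nonlinearity"] = net.nonlinearity
        f.attrs["tau"] = net.tau
        f.attrs["sigma"] = net.noise_sigma
        f.attrs["kind"] = net.kind
        f.attrs["init_bound"] = net.init_bound
        for key, val in (provenance or {}).items():
            f.attrs[f"prov_{key}"] = val


def load_attractor_net(path) -> AttractorNet:
    with h5py.File(path, "r") as f:
        for name in ("W", "b", "X0", "readout"):
            if name not in f:
                raise FormatError(f"missing dataset /{name} in {path}")
        return AttractorNet(
            weights=f["W"][()], bias=f["b"][()], init_states=f["X0"][()],
            readout_weights=f["readout"][()], readout_bias=f["readout_bias"][()],
            tau=float(f.attrs["tau"]), noise_sigma=float(f.attrs["sigma"]),
            kind=str(f.attrs["kind"]), init_bound=float(f.attrs["init_bound"]))


def save_lds_fit(path, fit: LDSFit, provenance: dict | None = None) -> None:
    """Write /A_d and /pca_basis with D, dt, window, ridge attrs."""
    with h5py.File(path, "w") as f:
        f.create_dataset("A_d", data=fit.A_d)
        f.create_dataset("pca_basis", data=fit.pca_basis)
        f.attrs["D"] = fit.dim
        f.attrs["dt"] = fit.dt
        f.attrs["window"] = list(fit.window)
        f.attrs["ridge"] = fit.ridge
        for key, val in (provenance or {}).items():
            f.attrs[f"prov_{key}"] = val


def load_lds_fit(path) -> LDSFit:
    with h5py.File(path, "r") as f:
        if "A_d" not in f:
            raise FormatError(f"missing dataset /A_d in {path}")
        w = f.attrs["window"]
        return LDSFit(dim=int(f.attrs["D"]), pca_basis=f["pca_basis"][()],
                      A_d=f["A_d"][()], dt=float(f.attrs["dt"]),
                      window=(float(w[0]), float(w[1])),
                      ridge=float(f.attrs["ridge"]))
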