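"""HDF5 / CSV serialization of phantoms, fields, and channel data.

All volumetric objects share one chunked HDF5 container layout: a group
per object with datasets for arrays and attributes for scalars, so a
phantom, its fluence, temperature snapshots, and RF data can live in the
same file.
"""

from __future__ import annotations

from dataclasses import fields as dc_fields

import h5py
import numpy as np
import pandas as pd

from .phantom import TissueProperties, VoxelGrid
from .thermal import HeatSourceField, TemperatureField
from .optics import FluenceField, BeamSpec
from .acoustics import PressureField, RFData

__all__ = [
    "save_phantom", "load_phantom",
    "save_field", "load_field",
    "save_rf", "load_rf",
    "trajectories_to_csv",
]

_PROP_FIELDS = [f.name for f in dc_fields(TissueProperties)]


def save_phantom(path, grid: VoxelGrid, group: str = "phantom") -> None:
    """Write region labels, per-property maps, and geometry attributes."""
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("region_labels", data=grid.region_labels,
                         chunks=True, compression="gzip")
        g.attrs["dl"] = grid.dl
        g.attrs["origin"] = grid.origin
        props = g.create_group("props")
        for label, tp in grid.props.items():
            row = props.create_group(str(label))
            for name in _PROP_FIELDS:
                row.attrs[name] = getattr(tp, name)
        for name in _PROP_FIELDS:
            g.create_dataset(f"maps/{name}", data=grid.property_map(name),
                             chunks=True, compression="gzip")


def load_phantom(path, group: str = "phantom") -> VoxelGrid:
    with h5py.File(path, "r") as f:
        g = f[group]
        labels = g["region_labels"][()]
        props = {}
        for label, row in g["props"].items():
            props[int(label)] = TissueProperties(
                **{name: float(row.attrs[name]) for name in _PROP_FIELDS})
        return VoxelGrid(shape=labels.shape, dl=float(g.attrs["dl"]),
                         region_labels=labels, props=props,
                         origin=tuple(g.attrs["origin"]))


def save_field(path, field, group: str) -> None:
    """Write a fluence / heat-source / temperature / pressure field."""
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        if isinstance(field, FluenceField):
            g.create_dataset("phi", data=field.phi, chunks=True,
                             compression="gzip")
            g.attrs["kind"] = "fluence"
            g.attrs["n_photons"] = field.n_photons
            if field.seed is not None:
                g.attrs["seed"] = field.seed
            for name in ("profile", "diameter", "wavelength",
                         "power_or_energy", "mode"):
                g.attrs[f"beam_{name}"] = getattr(field.beam, name)
        elif isinstance(field, HeatSourceField):
            g.create_dataset("S", data=field.S, chunks=True, compression="gzip")
            g.attrs["kind"] = "heat_source"
        elif isinstance(field, TemperatureField):
            g.create_dataset("T", data=field.T, chunks=True, compression="gzip")
            g.attrs["kind"] = "temperature"
            g.attrs["time"] = field.time
        elif isinstance(field, PressureField):
            g.create_dataset("p0", data=field.p0, chunks=True,
                             compression="gzip")
            g.attrs["kind"] = "pressure"
        else:
            raise TypeError(f"unsupported field type {type(field).__name__}")


def load_field(path, group: str):
    with h5py.File(path, "r") as f:
        g = f[group]
        kind = g.attrs["kind"]
        if kind == "fluence":
            beam = BeamSpec(
                profile=str(g.attrs["beam_profile"]),
                diameter=float(g.attrs["beam_diameter"]),
                wavelength=float(g.attrs["beam_wavelength"]),
                power_or_energy=float(g.attrs["beam_power_or_energy"]),
                mode=str(g.attrs["beam_mode"]))
            return FluenceField(phi=g["phi"][()], beam=beam,
                                n_photons=int(g.attrs.get("n_photons", 0)),
                                seed=int(g.attrs["seed"]) if "seed" in g.attrs else None)
        if kind == "heat_source":
            return HeatSourceField(S=g["S"][()])
        if kind == "temperature":
            return TemperatureField(T=g["T"][()], time=float(g.attrs["time"]))
        if kind == "pressure":
            return PressureField(p0=g["p0"][()])
        raise ValueError(f"unknown field kind {kind!r}")


def save_rf(path, rf: RFData, array=None, group: str = "rf") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("samples", data=rf.samples, chunks=True,
                         compression="gzip")
        g.attrs["dt_sample"] = rf.dt_sample
        g.attrs["t0"] = rf.t0
        if array is not None:
            g.create_dataset("element_positions", data=array.element_positions)
            g.attrs["center_frequency"] = array.center_frequency
            g.attrs["sampling_rate"] = array.sampling_rate


def load_rf(path, group: str = "rf") -> RFData:
    with h5py.File(path, "r") as f:
        g = f[group]
        return RFData(samples=g["samples"][()],
                      dt_sample=float(g.attrs["dt_sample"]),
                      t0=float(g.attrs["t0"]))


def trajectories_to_csv(path, trajectories: pd.DataFrame) -> None:
    """Write fusion trajectories (time, point, truth, model, pa, fused)."""
    trajectories.to_csv(path, index=False)


def save_calibration_table(path, temps, amplitudes) -> None:
    """Water-bath sweep as CSV: temperature plus one amplitude column per AOP."""
    amps = np.atleast_2d(np.asarray(amplitudes, dtype=float).T).T
    cols = {"temperature_C": np.asarray(temps, dtype=float)}
    for m in range(amps.shape[1]):
        cols[f"amplitude_aop{m}"] = amps[:, m]
    pd.DataFrame(cols).to_csv(path, index=False)


def load_calibration_table(path):
    df = pd.read_csv(path)
    temps = df["temperature_C"].to_numpy()
    amps = df[[c for c in df.columns if c.startswith("amplitude_")]].to_numpy()
    return temps, amps


def save_calibration(path, cal, provenance: dict | None = None) -> None:
    """Calibration model as a small YAML document with provenance fields."""
    import yaml

    doc = {
        "slope_coeff_per_K": float(cal.slope_coeff),
        "T0_C": float(cal.T0),
        "fit_r": None if cal.fit_r is None else float(cal.fit_r),
        "source": cal.source,
        "provenance": provenance or {},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_calibration(path):
    import yaml

    from .thermometry import CalibrationModel

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return CalibrationModel(slope_coeff=doc["slope_coeff_per_K"],
                            T0=doc["T0_C"], fit_r=doc.get("fit_r"),
                            source=doc.get("source", "configured"))
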