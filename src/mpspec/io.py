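"""Run container: self-describing HDF5 persistence for acquisitions and products.

One file per run.  The layout (schema version 1):

    /                       attrs: schema_version, seed, tool_version,
                            config (JSON), particle (JSON, if synthetic)
    /tf/frequency           calibration grid, Hz
    /tf/response            complex response, V per Am^2
    /measurements/m0000     one group per measurement, datasets rx_voltage,
                            drive_monitor, bias_monitor, bmon; attrs
                            sample_state, index
    /products/<name>        analysis products (arrays), free-form attrs

Writes are deterministic: no timestamps are embedded unless explicitly
passed, so identical runs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .particle import ParticleModel
from .simulate import AcquisitionConfig, InstrumentModel, Measurement, MeasurementSet
from .transfer import TransferFunction

__all__ = ["SCHEMA_VERSION", "write_run", "read_run", "loop_to_csv", "read_loop_csv"]

SCHEMA_VERSION = 1
TOOL_VERSION = "0.1.0"


class SchemaError(RuntimeError):
    """Container schema version is newer than this reader understands."""


def _dset(group: h5py.Group, name: str, data) -> None:
    group.create_dataset(name, data=np.asarray(data), track_times=False)


def write_run(
    mset: MeasurementSet,
    path,
    *,
    products: dict[str, np.ndarray] | None = None,
    timestamp: str | None = None,
) -> Path:
    """Persist a measurement set (and optional analysis products) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["tool_version"] = TOOL_VERSION
        f.attrs["seed"] = mset.seed
        f.attrs["config"] = json.dumps(dataclasses.asdict(mset.config))
        if mset.particle is not None:
            f.attrs["particle"] = json.dumps(
                {k: v for k, v in dataclasses.asdict(mset.particle).items() if v is not None}
            )
        inst = mset.instrument
        f.attrs["instrument"] = json.dumps(
            {
                "noise_density": inst.noise_density,
                "feedthrough_moment": inst.feedthrough_moment,
                "feedthrough_third_dbc": inst.feedthrough_third_dbc,
                "drive_coil_sensitivity": inst.drive_coil_sensitivity,
                "bias_coil_sensitivity": inst.bias_coil_sensitivity,
                "bmon_gain": inst.bmon_gain,
                "drift_amplitude_rate": inst.drift.amplitude_drift_rate,
                "drift_phase_rate": inst.drift.phase_drift_rate,
            }
        )
        if timestamp is not None:
            f.attrs["timestamp"] = timestamp
        tf_group = f.create_group("tf")
        _dset(tf_group, "frequency", inst.tf.frequency_grid)
        _dset(tf_group, "response", inst.tf.response)
        meas_group = f.create_group("measurements")
        for m in mset.measurements:
            g = meas_group.create_group(f"m{m.index:04d}")
            g.attrs["sample_state"] = m.sample_state
            g.attrs["index"] = m.index
            _dset(g, "rx_voltage", m.rx_voltage)
            _dset(g, "drive_monitor", m.drive_monitor)
            _dset(g, "bias_monitor", m.bias_monitor)
            _dset(g, "bmon", m.bmon)
        if products:
            prod_group = f.create_group("products")
            for name, data in products.items():
                _dset(prod_group, name, data)
    return path


def read_run(path) -> MeasurementSet:
    """Load a run container written by :func:`write_run`."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs["schema_version"])
        if version > SCHEMA_VERSION:
            raise SchemaError(
                f"container schema v{version} is newer than supported v{SCHEMA_VERSION}"
            )
        config = AcquisitionConfig(**json.loads(f.attrs["config"]))
        particle = None
        if "particle" in f.attrs:
            particle = ParticleModel(**json.loads(f.attrs["particle"]))
        tf = TransferFunction(f["tf/frequency"][:], f["tf/response"][:])
        inst_meta = json.loads(f.attrs["instrument"])
        from .simulate import DriftModel

        instrument = InstrumentModel(
            tf=tf,
            drift=DriftModel(
                inst_meta["drift_amplitude_rate"], inst_meta["drift_phase_rate"]
            ),
            noise_density=inst_meta["noise_density"],
            feedthrough_moment=inst_meta["feedthrough_moment"],
            feedthrough_third_dbc=inst_meta["feedthrough_third_dbc"],
            drive_coil_sensitivity=inst_meta["drive_coil_sensitivity"],
            bias_coil_sensitivity=inst_meta["bias_coil_sensitivity"],
            bmon_gain=inst_meta["bmon_gain"],
        )
        measurements = []
        for name in sorted(f["measurements"]):
            g = f["measurements"][name]
            measurements.append(
                Measurement(
                    rx_voltage=g["rx_voltage"][:],
                    drive_monitor=g["drive_monitor"][:],
                    bias_monitor=g["bias_monitor"][:],
                    bmon=g["bmon"][:],
                    sample_state=str(g.attrs["sample_state"]),
                    index=int(g.attrs["index"]),
                )
            )
        seed = int(f.attrs["seed"])
    return MeasurementSet(config, instrument, measurements, seed, particle)


def loop_to_csv(loop, path) -> Path:
    """Write a hysteresis loop as a two-column CSV (H_mT, m_Am2)."""
    path = Path(path)
    loop.to_frame().to_csv(path, index=False)
    return path


def read_loop_csv(path):
    """Read a loop CSV back into a :class:`~mpspec.relaxometry.HysteresisLoop`."""
    from .relaxometry import HysteresisLoop

    frame = pd.read_csv(path)
    return HysteresisLoop(
        frame["H_mT"].to_numpy(), frame["m_Am2"].to_numpy(), sample_interval=5e-7
    )
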