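"""Readers and writers: CSV, NetCDF and SOFA import for directional data.

Every writer has a matching reader and round-trips exactly at CSV precision.
NetCDF files are written through xarray's scipy backend (NetCDF3).  SOFA
(Spatially Oriented Format for Acoustics) files — HDF5 containers of
measured impulse responses — can be imported as a per-frequency magnitude
field mapped onto the active partition by nearest-direction lookup.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .entropy import EntropyMap
from .fields import DirectionalField
from .sphere import SpherePartition
from .templates import TemplateSet

__all__ = [
    "partition_to_csv",
    "partition_from_csv",
    "field_to_csv",
    "field_from_csv",
    "fields_to_netcdf",
    "fields_from_netcdf",
    "templates_to_csv",
    "templates_to_netcdf",
    "templates_from_netcdf",
    "ensemble_to_wav",
    "ensemble_from_wav",
    "ensemble_gains_to_csv",
    "entropy_map_to_csv",
    "entropy_map_to_netcdf",
    "entropy_map_from_netcdf",
    "covariance_to_csv",
    "import_directional_field",
    "import_sofa_field",
]


def partition_to_csv(partition: SpherePartition, path: str | Path) -> None:
    pd.DataFrame(
        {
            "cell_id": np.arange(partition.n_cells),
            "azimuth_deg": partition.cell_centers[:, 0],
            "elevation_deg": partition.cell_centers[:, 1],
            "solid_angle_sr": partition.cell_solid_angle_sr,
        }
    ).to_csv(path, index=False)


def partition_from_csv(path: str | Path) -> SpherePartition:
    df = pd.read_csv(path)
    centers = df.sort_values("cell_id")[["azimuth_deg", "elevation_deg"]].to_numpy()
    return SpherePartition(len(df), centers)


def field_to_csv(field: DirectionalField, path: str | Path) -> None:
    pd.DataFrame(
        {
            "cell_id": np.arange(field.partition.n_cells),
            "azimuth_deg": field.partition.cell_centers[:, 0],
            "elevation_deg": field.partition.cell_centers[:, 1],
            "frequency_khz": field.frequency_khz,
            "gain_db": field.gain_db,
            "role": field.role,
        }
    ).to_csv(path, index=False)


def field_from_csv(path: str | Path, partition: SpherePartition) -> DirectionalField:
    df = pd.read_csv(path)
    if "gain_db" not in df.columns:
        raise ValueError("field CSV must carry gains in a 'gain_db' column")
    missing = set(range(partition.n_cells)) - set(df["cell_id"].astype(int))
    if missing:
        raise ValueError(f"field CSV is missing cell id {sorted(missing)[0]}")
    df = df.sort_values("cell_id")
    return DirectionalField(
        partition,
        float(df["frequency_khz"].iloc[0]),
        df["gain_db"].to_numpy(),
        str(df["role"].iloc[0]),
    )


def _fields_dataset(fields: list[DirectionalField]) -> xr.Dataset:
    part = fields[0].partition
    freqs = sorted({f.frequency_khz for f in fields})
    roles = sorted({f.role for f in fields})
    data = np.full((len(roles), len(freqs), part.n_cells), np.nan)
    for f in fields:
        data[roles.index(f.role), freqs.index(f.frequency_khz)] = f.gain_db
    return xr.Dataset(
        {"gain_db": (("role", "frequency_khz", "cell"), data)},
        coords={
            "role": roles,
            "frequency_khz": freqs,
            "cell": np.arange(part.n_cells),
            "azimuth_deg": ("cell", part.cell_centers[:, 0]),
            "elevation_deg": ("cell", part.cell_centers[:, 1]),
        },
    )


def fields_to_netcdf(fields: list[DirectionalField], path: str | Path) -> None:
    _fields_dataset(fields).to_netcdf(path, engine="scipy")


def fields_from_netcdf(path: str | Path) -> list[DirectionalField]:
    with xr.open_dataset(path, engine="scipy") as ds:
        centers = np.column_stack(
            [ds["azimuth_deg"].values, ds["elevation_deg"].values]
        )
        part = SpherePartition(centers.shape[0], centers)
        out = []
        for role in ds["role"].values:
            for f in ds["frequency_khz"].values:
                g = ds["gain_db"].sel(role=role, frequency_khz=f).values
                if not np.all(np.isnan(g)):
                    out.append(DirectionalField(part, float(f), g, str(role)))
    return out


def templates_to_csv(ts: TemplateSet, path: str | Path) -> None:
    n = ts.partition.n_cells
    cols = {
        "cell_id": np.arange(n),
        "frequency_khz": ts.frequency_khz,
        "rel_gain_db": ts.position_gain_db - ts.position_gain_db.max(),
    }
    for j in range(ts.n_elements):
        cols[f"element_{j + 1}"] = ts.templates[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def templates_to_netcdf(ts: TemplateSet, path: str | Path) -> None:
    part = ts.partition
    ds = xr.Dataset(
        {
            "template_db": (("cell", "element"), ts.templates),
            "position_gain_db": ("cell", ts.position_gain_db),
        },
        coords={
            "cell": np.arange(part.n_cells),
            "element": np.arange(1, ts.n_elements + 1),
            "azimuth_deg": ("cell", part.cell_centers[:, 0]),
            "elevation_deg": ("cell", part.cell_centers[:, 1]),
        },
        attrs={
            "frequency_khz": ts.frequency_khz,
            "max_raw_gain_db": ts.max_raw_gain_db,
        },
    )
    ds.to_netcdf(path, engine="scipy")


def templates_from_netcdf(path: str | Path) -> TemplateSet:
    from .templates import EarSweepProtocol

    with xr.open_dataset(path, engine="scipy") as ds:
        centers = np.column_stack(
            [ds["azimuth_deg"].values, ds["elevation_deg"].values]
        )
        part = SpherePartition(centers.shape[0], centers)
        return TemplateSet(
            frequency_khz=float(ds.attrs["frequency_khz"]),
            partition=part,
            templates=ds["template_db"].values,
            position_gain_db=ds["position_gain_db"].values,
            max_raw_gain_db=float(ds.attrs["max_raw_gain_db"]),
            protocol=EarSweepProtocol(),
        )


def ensemble_to_wav(ensemble, path: str | Path) -> None:
    """Write echo traces as a multi-channel float WAV (one channel per echo)."""
    from scipy.io import wavfile

    wavfile.write(
        path,
        int(ensemble.sampling_rate_hz),
        np.ascontiguousarray(ensemble.traces.T, dtype=np.float32),
    )


def ensemble_from_wav(path: str | Path, carrier_khz: float):
    from scipy.io import wavfile

    from .flutter import EchoEnsemble

    fs, data = wavfile.read(path)
    if data.ndim == 1:
        data = data[:, None]
    return EchoEnsemble(np.asarray(data.T, dtype=float), float(fs), carrier_khz)


def ensemble_gains_to_csv(ensemble, frequency_khz: float, path: str | Path) -> None:
    """Write the per-echo dB gains at one frequency."""
    from .flutter import echo_gains_db

    pd.DataFrame(
        {
            "echo": np.arange(ensemble.n_echoes),
            "frequency_khz": frequency_khz,
            "gain_db": echo_gains_db(ensemble, frequency_khz),
        }
    ).to_csv(path, index=False)


def entropy_map_to_csv(emap: EntropyMap, path: str | Path) -> None:
    df = emap.data.to_dataframe().reset_index()
    df = df.rename(columns={"expected_entropy_bits": "entropy_bits", "cell": "cell_id"})
    df.to_csv(path, index=False)


def entropy_map_to_netcdf(emap: EntropyMap, path: str | Path) -> None:
    ds = emap.data.to_dataset()
    ds.attrs["n_realizations"] = emap.n_realizations
    ds = ds.assign_coords(
        azimuth_deg=("cell", emap.partition.cell_centers[:, 0]),
        elevation_deg=("cell", emap.partition.cell_centers[:, 1]),
    )
    ds.to_netcdf(path, engine="scipy")


def entropy_map_from_netcdf(path: str | Path) -> EntropyMap:
    with xr.open_dataset(path, engine="scipy") as ds:
        centers = np.column_stack(
            [ds["azimuth_deg"].values, ds["elevation_deg"].values]
        )
        part = SpherePartition(centers.shape[0], centers)
        data = ds["expected_entropy_bits"].load()
        n_real = int(ds.attrs.get("n_realizations", 0))
    return EntropyMap(data, part, n_real)


def covariance_to_csv(cov, path: str | Path) -> None:
    pd.DataFrame(cov.matrix).to_csv(path, index=False, header=False)


def import_directional_field(
    path: str | Path,
    partition: SpherePartition,
    format: str | None = None,
    frequency_khz: float | None = None,
) -> DirectionalField:
    """Load a directional field from CSV, NetCDF or SOFA onto the partition."""
    path = Path(path)
    fmt = format or {".csv": "csv", ".nc": "netcdf", ".sofa": "sofa"}.get(
        path.suffix.lower()
    )
    if fmt == "csv":
        return field_from_csv(path, partition)
    if fmt == "netcdf":
        fields = fields_from_netcdf(path)
        if frequency_khz is not None:
            fields = [f for f in fields if f.frequency_khz == frequency_khz]
        if not fields:
            raise ValueError("no matching field in NetCDF file")
        return fields[0]
    if fmt == "sofa":
        if frequency_khz is None:
            raise ValueError("SOFA import needs a target frequency")
        return import_sofa_field(path, partition, frequency_khz)
    raise ValueError(f"unrecognized field format {fmt!r}")


def import_sofa_field(
    path: str | Path,
    partition: SpherePartition,
    frequency_khz: float,
    receiver: int = 0,
    role: str = "hearing_left",
    floor_db: float = -60.0,
) -> DirectionalField:
    """Map a measured SOFA HRTF onto the partition at one frequency.

    Reads ``Data.IR`` and ``SourcePosition`` (SOFA spherical convention:
    azimuth 0..360 counterclockwise, elevation -90..90), converts the IR of
    the chosen receiver to a magnitude (dB) at the nearest FFT bin to
    ``frequency_khz``, keeps frontal-hemisphere sources only (rear sources
    are discarded with a warning) and assigns each partition cell the gain
    of the nearest measured direction.
    """
    import h5py

    with h5py.File(path, "r") as fh:
        pos = np.asarray(fh["SourcePosition"][:], dtype=float)
        ir = np.asarray(fh["Data.IR"][:], dtype=float)
        fs = float(np.ravel(fh["Data.SamplingRate"][:])[0])
    az = pos[:, 0].copy()
    az[az > 180.0] -= 360.0
    az = -az  # SOFA azimuth is counterclockwise; ours is positive-right
    el = pos[:, 1]
    frontal = (np.abs(az) <= 90.0) & (np.abs(el) <= 90.0)
    if not np.all(frontal):
        warnings.warn(
            f"discarding {int((~frontal).sum())} rear-hemisphere SOFA sources",
            stacklevel=2,
        )
    if not np.any(frontal):
        raise ValueError("SOFA file has no frontal-hemisphere sources")
    spec = np.fft.rfft(ir[frontal, receiver, :], axis=-1)
    bins = np.fft.rfftfreq(ir.shape[-1], d=1.0 / fs)
    k = int(np.argmin(np.abs(bins - frequency_khz * 1e3)))
    mag = np.abs(spec[:, k])
    gains = 20.0 * np.log10(np.maximum(mag, 10.0 ** (floor_db / 20.0)))
    azr, elr = np.deg2rad(az[frontal]), np.deg2rad(el[frontal])
    vec = np.column_stack(
        [np.cos(elr) * np.cos(azr), np.cos(elr) * np.sin(azr), np.sin(elr)]
    )
    nearest = np.argmax(partition.unit_vectors @ vec.T, axis=1)
    return DirectionalField(
        partition, frequency_khz, np.maximum(gains[nearest], floor_db), role, floor_db
    )
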