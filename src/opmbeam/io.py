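"""File formats: NIfTI statistical maps, HDF5 epoch containers, YAML config.

Maps are written as NIfTI-1 float32 volumes whose affine encodes the source
grid (isotropic spacing, world coordinates in mm); out-of-mask voxels are
NaN, which is how the in-head mask round-trips.  Epoched sessions live in an
HDF5 container with the epoch tensor, labels, time axis, channel table and
ground-truth group, plus a JSON sidecar holding the full config and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .geometry import SensorArray, SourceGrid, SphereHeadModel
from .inference import StatMap
from .simulate import EpochedData, GroundTruth

try:  # nibabel is the one neuroimaging-specific dependency
    import nibabel as nib
except ImportError as exc:  # pragma: no cover
    raise ImportError("opmbeam map I/O requires nibabel") from exc


def write_map(stat_map: StatMap, path) -> None:
    """Save a StatMap as NIfTI-1 float32 with an mm-scaled isotropic affine."""
    grid = stat_map.grid
    spacing_mm = grid.spacing * 1e3
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    affine[:3, 3] = grid.origin * 1e3
    img = nib.Nifti1Image(stat_map.values.astype(np.float32), affine)
    img.header["descrip"] = f"opmbeam:{stat_map.kind}".encode()
    nib.save(img, str(path))


def read_map(path, expected_spacing_mm: float | None = None) -> StatMap:
    """Load a NIfTI map written by :func:`write_map`.

    Rejects non-diagonal or anisotropic affines, and (when
    ``expected_spacing_mm`` is given) any spacing that does not match the
    study grid — maps from a different grid cannot enter a conjunction.
    """
    img = nib.load(str(path))
    affine = img.affine
    off_diag = affine[:3, :3] - np.diag(np.diag(affine[:3, :3]))
    diag = np.diag(affine)[:3]
    if np.any(np.abs(off_diag) > 1e-6) or not np.allclose(diag, diag[0]):
        raise ValueError(
            f"{path}: only axis-aligned isotropic affines are supported"
        )
    spacing_mm = float(diag[0])
    if expected_spacing_mm is not None and not np.isclose(
        spacing_mm, expected_spacing_mm
    ):
        raise ValueError(
            f"{path}: voxel spacing is {spacing_mm:g} mm, expected "
            f"{expected_spacing_mm:g} mm; refusing to mix grids"
        )
    values = np.asarray(img.dataobj, dtype=float)
    descrip = img.header["descrip"].tobytes().decode(errors="ignore").rstrip("\x00")
    kind = descrip.split(":", 1)[1] if descrip.startswith("opmbeam:") else "F"
    origin = affine[:3, 3] / 1e3
    grid = SourceGrid(origin, spacing_mm / 1e3, values.shape, np.isfinite(values))
    return StatMap(grid, values, kind)


# --------------------------------------------------------------------------
# HDF5 session container
# --------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def _write_sensors(group: h5py.Group, sensors: SensorArray) -> None:
    group.create_dataset("name", data=np.array(sensors.names, dtype=object), dtype=_STR)
    group.create_dataset("role", data=np.array(sensors.roles, dtype=object), dtype=_STR)
    group.create_dataset("position", data=sensors.positions)
    group.create_dataset("orientation", data=sensors.orientations)


def _read_sensors(group: h5py.Group) -> SensorArray:
    return SensorArray(
        [s.decode() if isinstance(s, bytes) else s for s in group["name"][()]],
        group["position"][()],
        group["orientation"][()],
        np.array([s.decode() if isinstance(s, bytes) else s for s in group["role"][()]],
                 dtype=object),
    )


def save_session(
    path,
    epochs: EpochedData,
    truth: GroundTruth | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write a session to HDF5 (+ JSON sidecar with config and seed)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data)
        f.create_dataset("labels", data=np.array(epochs.labels, dtype=object),
                         dtype=_STR)
        f.create_dataset("time", data=epochs.times)
        f.attrs["sample_rate"] = epochs.sfreq
        _write_sensors(f.create_group("channels"), epochs.sensors)
        if truth is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("source_position", data=truth.source_position)
            g.create_dataset("source_orientation", data=truth.source_orientation)
            g.create_dataset("gains", data=truth.gains)
            g.create_dataset("source_traces", data=truth.source_traces)
            g.create_dataset("interference_components",
                             data=truth.interference_components)
            g.create_dataset("mixing", data=truth.mixing)
            g.create_dataset("labels", data=np.array(truth.labels, dtype=object),
                             dtype=_STR)
            g.attrs["condition_power"] = json.dumps(truth.condition_power)
            g.attrs["head_center"] = list(truth.head.center)
            g.attrs["head_radius"] = truth.head.radius
            _write_sensors(g.create_group("scalp_array"), truth.scalp_array)
    if config is not None or seed is not None:
        sidecar = {"config": config, "seed": seed}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_session(path) -> tuple[EpochedData, GroundTruth | None]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        sensors = _read_sensors(f["channels"])
        labels = np.array(
            [s.decode() if isinstance(s, bytes) else s for s in f["labels"][()]],
            dtype=object,
        )
        epochs = EpochedData(f["epochs"][()], labels, float(f.attrs["sample_rate"]),
                             sensors)
        truth = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            t_labels = np.array(
                [s.decode() if isinstance(s, bytes) else s for s in g["labels"][()]],
                dtype=object,
            )
            truth = GroundTruth(
                source_position=g["source_position"][()],
                source_orientation=g["source_orientation"][()],
                gains=g["gains"][()],
                condition_power=json.loads(g.attrs["condition_power"]),
                source_traces=g["source_traces"][()],
                interference_components=g["interference_components"][()],
                mixing=g["mixing"][()],
                labels=t_labels,
                scalp_array=_read_sensors(g["scalp_array"]),
                head=SphereHeadModel(tuple(g.attrs["head_center"]),
                                     float(g.attrs["head_radius"])),
            )
    return epochs, truth


# --------------------------------------------------------------------------
# YAML config
# --------------------------------------------------------------------------

def save_config(config_dict: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_dict, sort_keys=True))


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
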