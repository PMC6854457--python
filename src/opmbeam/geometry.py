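"""Sensor arrays, spherical head model and volumetric source grids.

All coordinates are right-handed and in metres internally; statistical maps
are exported with world coordinates in millimetres.  The head is modelled as a
homogeneous conducting sphere (the forward model in :mod:`opmbeam.forward` is
exact for this geometry).  Scalp sensors are single-axis magnetometers placed
a fixed standoff above the sphere surface with radial sensitive axes, as in a
typical OPM scanner-cast; a small reference array sits behind the head and
sees only environmental interference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SCALP = "scalp"
REFERENCE = "reference"

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0
_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class SphereHeadModel:
    """Homogeneous conducting sphere: centre (m) and conductor radius (m)."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 0.09

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError("head radius must be positive")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def center_arr(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass
class SensorArray:
    """Positions, unit sensitive axes and roles of single-axis magnetometers."""

    names: list[str]
    positions: np.ndarray      # (n, 3) metres
    orientations: np.ndarray   # (n, 3) unit vectors
    roles: np.ndarray          # (n,) "scalp" | "reference"

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        self.roles = np.asarray(self.roles, dtype=object)
        self.names = list(self.names)
        n = len(self.names)
        if self.positions.shape != (n, 3) or self.orientations.shape != (n, 3):
            raise ValueError("positions/orientations must be (n_channels, 3)")
        if self.roles.shape != (n,):
            raise ValueError("one role per channel required")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("orientation vectors must have unit norm")
        bad = set(self.roles) - {SCALP, REFERENCE}
        if bad:
            raise ValueError(f"unknown channel roles: {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def select(self, role: str) -> "SensorArray":
        keep = np.flatnonzero(self.roles == role)
        return SensorArray(
            [self.names[i] for i in keep],
            self.positions[keep],
            self.orientations[keep],
            self.roles[keep],
        )

    @classmethod
    def concat(cls, *arrays: "SensorArray") -> "SensorArray":
        return cls(
            [n for a in arrays for n in a.names],
            np.vstack([a.positions for a in arrays]),
            np.vstack([a.orientations for a in arrays]),
            np.concatenate([a.roles for a in arrays]),
        )

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path, head: SphereHeadModel | None = None) -> None:
        """Write a TSV (name, role, x, y, z, ox, oy, oz; metres).

        If ``head`` is given, its parameters go to a JSON sidecar next to the
        table.
        """
        df = pd.DataFrame(
            {
                "name": self.names,
                "role": self.roles,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "ox": self.orientations[:, 0],
                "oy": self.orientations[:, 1],
                "oz": self.orientations[:, 2],
            }
        )
        path = Path(path)
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
        if head is not None:
            sidecar = path.with_suffix(".json")
            sidecar.write_text(
                json.dumps({"head_center_m": list(head.center), "head_radius_m": head.radius})
            )

    @classmethod
    def from_tsv(cls, path) -> "SensorArray":
        df = pd.read_csv(path, sep="\t")
        return cls(
            df["name"].astype(str).tolist(),
            df[["x", "y", "z"]].to_numpy(float),
            df[["ox", "oy", "oz"]].to_numpy(float),
            df["role"].to_numpy(object),
        )


def head_model_from_sidecar(path) -> SphereHeadModel:
    meta = json.loads(Path(path).read_text())
    return SphereHeadModel(tuple(meta["head_center_m"]), meta["head_radius_m"])


def make_scalp_array(
    n_sensors: int,
    head: SphereHeadModel,
    coverage: dict | None = None,
    seed: int = 0,
    standoff: float = 0.0065,
) -> SensorArray:
    """Quasi-uniform radial scalp array over a spherical cap.

    Sensors sit ``standoff`` metres above the sphere surface (default 6.5 mm,
    a typical OPM cell-to-scalp distance) on a Fibonacci spiral covering the
    cap above ``z_min_frac * radius`` (default -0.4, mimicking the coverage of
    a scanner-cast that excludes the neck/face).  The seed only rotates the
    spiral about z, so arrays are deterministic per seed.
    """
    if not (1 <= n_sensors <= 256):
        raise ValueError("n_sensors must be between 1 and 256")
    coverage = dict(coverage or {})
    z_min_frac = float(coverage.pop("z_min_frac", -0.4))
    if coverage:
        raise ValueError(f"unknown coverage keys: {sorted(coverage)}")

    rng = np.random.default_rng(seed)
    azimuth_offset = rng.uniform(0.0, 2.0 * np.pi)

    if n_sensors == 1:
        z_frac = np.array([1.0])
        azimuth = np.array([0.0])
    else:
        t = (np.arange(n_sensors) + 0.5) / n_sensors
        z_frac = 1.0 - (1.0 - z_min_frac) * t
        azimuth = 2.0 * np.pi * np.arange(n_sensors) / _GOLDEN**2 + azimuth_offset

    rho = np.sqrt(np.clip(1.0 - z_frac**2, 0.0, None))
    direction = np.column_stack(
        [rho * np.cos(azimuth), rho * np.sin(azimuth), z_frac]
    )
    positions = head.center_arr + (head.radius + standoff) * direction
    names = [f"scalp{i:02d}" for i in range(n_sensors)]
    roles = np.array([SCALP] * n_sensors, dtype=object)
    return SensorArray(names, positions, direction, roles)


def make_reference_array(
    head: SphereHeadModel, offset_m: float = 0.10, n_ref: int = 4
) -> SensorArray:
    """Reference sensor cluster behind the head (-y direction).

    Orientations cycle through the three cardinal axes, so with ``n_ref >= 4``
    one axis is duplicated at a small spatial offset; the cluster spread is
    ~1.2 cm, keeping every sensor >= ``offset_m`` behind the scalp surface.
    """
    if offset_m < 0.05:
        raise ValueError("reference array offset must be at least 0.05 m behind the scalp")
    if n_ref < 1:
        raise ValueError("need at least one reference sensor")
    base = head.center_arr + np.array([0.0, -(head.radius + offset_m), 0.0])
    spread = 0.012
    positions = np.empty((n_ref, 3))
    orientations = np.empty((n_ref, 3))
    axes = np.eye(3)
    for i in range(n_ref):
        if i == 0:
            positions[i] = base
        else:
            angle = 2.0 * np.pi * i / n_ref
            positions[i] = base + spread * np.array([np.cos(angle), 0.0, np.sin(angle)])
        orientations[i] = axes[i % 3]
    names = [f"ref{i:02d}" for i in range(n_ref)]
    roles = np.array([REFERENCE] * n_ref, dtype=object)
    return SensorArray(names, positions, orientations, roles)


@dataclass
class SourceGrid:
    """Regular volumetric grid of candidate sources with an in-head mask.

    ``origin`` is the world coordinate (m) of voxel (0, 0, 0); voxel indices
    are 0-based; the flat ordering of in-mask voxels is C order.
    """

    origin: np.ndarray            # (3,) metres
    spacing: float                # metres, isotropic
    shape: tuple[int, int, int]
    mask: np.ndarray              # (nx, ny, nz) bool

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = float(self.spacing)
        self.shape = tuple(int(s) for s in self.shape)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.mask.shape != self.shape:
            raise ValueError("mask shape must match grid shape")

    @classmethod
    def centered_cube(
        cls, head: SphereHeadModel, spacing: float = 0.003, n: int = 30
    ) -> "SourceGrid":
        """Cube of ``n``³ voxels centred on the head, masked to the sphere interior."""
        origin = head.center_arr - spacing * (n - 1) / 2.0
        grid = cls(origin, spacing, (n, n, n), np.ones((n, n, n), dtype=bool))
        coords = grid.all_world_coords()
        inside = np.linalg.norm(coords - head.center_arr, axis=1) < head.radius
        grid.mask = inside.reshape(grid.shape)
        return grid

    # ------------------------------------------------------------- mappings
    def index_to_world(self, ijk) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(ijk, dtype=float)

    def world_to_index(self, world) -> np.ndarray:
        idx = np.rint((np.asarray(world, dtype=float) - self.origin) / self.spacing)
        return idx.astype(int)

    def all_world_coords(self) -> np.ndarray:
        ijk = np.indices(self.shape).reshape(3, -1).T
        return self.index_to_world(ijk)

    def in_mask_indices(self) -> np.ndarray:
        """(n_sources, 3) integer indices of in-mask voxels, C order."""
        return np.argwhere(self.mask)

    def in_mask_coords(self) -> np.ndarray:
        return self.index_to_world(self.in_mask_indices())

    @property
    def n_sources(self) -> int:
        return int(self.mask.sum())

    def embed(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter a flat in-mask vector into a full 3-D volume."""
        out = np.full(self.shape, fill, dtype=float)
        out[self.mask] = values
        return out

    def compatible(self, other: "SourceGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.isclose(self.spacing, other.spacing)
            and np.array_equal(self.mask, other.mask)
        )
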