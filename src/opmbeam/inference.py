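"""Group-level conjunction inference, FDR control and bootstrap stability.

Participant F maps are smoothed (9 mm FWHM Gaussian, renormalised over the
in-mask support), converted to upper-tail p values, and combined across
participants with the maximum-p conjunction statistic, which rejects the null
that NO participant shows an effect at a voxel.  Voxelwise multiplicity is
controlled with the Benjamini-Hochberg step-up at a conservative q.  Cluster
stability is quantified by resampling each participant's trials with
replacement, regenerating beamformer images, repeating the conjunction on
random image draws, and expressing per-voxel significance counts as a
percentage of all conjunctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .geometry import SourceGrid

VALUE_KINDS = ("F", "t", "p", "mask01", "percent")


@dataclass
class StatMap:
    """Values on a regular 3 mm-style grid; defined on in-mask voxels only."""

    grid: SourceGrid
    values: np.ndarray   # full 3-D volume; out-of-mask voxels are NaN
    kind: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("value volume must match the grid shape")
        if self.kind not in VALUE_KINDS:
            raise ValueError(f"unknown value kind {self.kind!r}")
        v = self.masked_values
        finite = v[np.isfinite(v)]
        if self.kind == "p" and finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("p values must lie in [0, 1]")
        if self.kind == "mask01" and finite.size and not np.all(np.isin(finite, (0.0, 1.0))):
            raise ValueError("mask maps must be 0/1 valued")
        if self.kind == "percent" and finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("percentage maps must lie in [0, 100]")

    @property
    def masked_values(self) -> np.ndarray:
        return self.values[self.grid.mask]

    def with_values(self, flat_values: np.ndarray, kind: str | None = None) -> "StatMap":
        return StatMap(self.grid, self.grid.embed(flat_values), kind or self.kind)

    def peak(self) -> tuple[np.ndarray, float]:
        """(world coordinate in m, value) of the in-mask maximum."""
        vals = self.masked_values
        idx = self.grid.in_mask_indices()
        best = int(np.nanargmax(vals))
        return self.grid.index_to_world(idx[best]), float(vals[best])


def _check_grids(maps) -> SourceGrid:
    grid = maps[0].grid
    for m in maps[1:]:
        if not grid.compatible(m.grid):
            raise ValueError("statistical maps are defined on different grids")
    return grid


def smooth_map(stat_map: StatMap, fwhm_mm: float = 9.0) -> StatMap:
    """Separable Gaussian smoothing restricted to the in-mask volume.

    sigma = fwhm / (2 sqrt(2 ln 2)) per axis; at mask boundaries the kernel is
    renormalised over the in-mask support (normalised convolution), so a
    constant map is exactly preserved.  ``fwhm_mm=0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("smoothing FWHM must be non-negative")
    if fwhm_mm == 0:
        return StatMap(stat_map.grid, stat_map.values.copy(), stat_map.kind)
    grid = stat_map.grid
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / (grid.spacing * 1e3)
    mask = grid.mask.astype(float)
    filled = np.where(grid.mask, stat_map.values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma_vox, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(mask, sigma_vox, mode="constant", cval=0.0)
    out = np.full(grid.shape, np.nan)
    out[grid.mask] = num[grid.mask] / den[grid.mask]
    return StatMap(grid, out, stat_map.kind)


def map_to_p(stat_map: StatMap, df: tuple[int, int]) -> StatMap:
    """Upper-tail F-distribution probability at each voxel."""
    df1, df2 = df
    if df1 < 1 or df2 < 1:
        raise ValueError("invalid degrees of freedom")
    p = stats.f.sf(stat_map.masked_values, df1, df2)
    return stat_map.with_values(p, "p")


def conjunction_p(p_maps: list[StatMap]) -> StatMap:
    """Maximum-p conjunction across participants.

    The voxelwise maximum of the participant p values is a valid p value for
    the conjunction null that no participant shows an effect there.
    """
    if len(p_maps) < 2:
        raise ValueError("conjunction requires at least two participants")
    grid = _check_grids(p_maps)
    stacked = np.stack([m.masked_values for m in p_maps])
    return StatMap(grid, grid.embed(stacked.max(axis=0)), "p")


def fdr_mask(p_map: StatMap, q: float = 0.005) -> StatMap:
    """Benjamini-Hochberg step-up over all in-mask voxels.

    Sort p ascending, find the largest k with p_(k) <= k q / m, and declare
    all voxels with p <= p_(k) significant; the mask is empty if no such k
    exists.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    p = p_map.masked_values
    m = p.size
    order = np.sort(p)
    thresh = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(order <= thresh)
    if passing.size == 0:
        sig = np.zeros(m)
    else:
        p_crit = order[passing[-1]]
        sig = (p <= p_crit).astype(float)
    return p_map.with_values(sig, "mask01")


@dataclass
class Cluster:
    label: int
    n_voxels: int
    peak_index: tuple[int, int, int]
    peak_world_mm: tuple[float, float, float]
    peak_value: float
    members: np.ndarray  # (n, 3) voxel indices


@dataclass
class ClusterReport:
    """Maximal 6-connected components of a significance mask with their peaks.

    Connectivity is face-adjacency (6 neighbours); peak ties break towards the
    lowest linear (C-order) voxel index.
    """

    clusters: list[Cluster] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": c.label,
                "n_voxels": c.n_voxels,
                "peak_x_mm": c.peak_world_mm[0],
                "peak_y_mm": c.peak_world_mm[1],
                "peak_z_mm": c.peak_world_mm[2],
                "peak_stat": c.peak_value,
            }
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows, columns=["cluster", "n_voxels", "peak_x_mm", "peak_y_mm",
                           "peak_z_mm", "peak_stat"],
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def clusters_and_peaks(mask: StatMap, stat: StatMap) -> ClusterReport:
    """Label 6-connected components of ``mask`` and report per-cluster peaks."""
    if not mask.grid.compatible(stat.grid):
        raise ValueError("mask and statistic maps are on different grids")
    binary = np.where(mask.grid.mask, np.nan_to_num(mask.values) > 0, False)
    structure = ndimage.generate_binary_structure(3, 1)  # faces only
    labels, n = ndimage.label(binary, structure=structure)
    report = ClusterReport()
    for lab in range(1, n + 1):
        members = np.argwhere(labels == lab)       # sorted by linear index
        vals = stat.values[tuple(members.T)]
        best = int(np.nanargmax(vals))              # first occurrence on ties
        peak_ijk = tuple(int(i) for i in members[best])
        world_mm = mask.grid.index_to_world(members[best]) * 1e3
        report.clusters.append(
            Cluster(
                label=lab,
                n_voxels=members.shape[0],
                peak_index=peak_ijk,
                peak_world_mm=tuple(float(w) for w in world_mm),
                peak_value=float(vals[best]),
                members=members,
            )
        )
    return report


@dataclass(frozen=True)
class BootstrapConfig:
    """Replicate counts for the bootstrap-conjunction stability analysis."""

    n_boot_per_participant: int = 100
    n_conjunctions: int = 500
    q: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.n_boot_per_participant < 1 or self.n_conjunctions < 1:
            raise ValueError("replicate counts must be at least 1")
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must lie in (0, 1)")


def bootstrap_images(localization, n_boot: int, seed: int) -> list[StatMap]:
    """Trial-resampled beamformer F images for one participant.

    Each replicate draws every condition's trials with replacement
    (independently per condition), then reruns covariance -> orientation ->
    weights -> power -> F on the resampled multiset.  ``localization`` is a
    fitted :class:`opmbeam.beamformer.Localization`.
    """
    rng = np.random.default_rng(seed)
    labels = localization.labels
    cond_idx = {c: np.flatnonzero(labels == c) for c in np.unique(labels)}
    images = []
    for _ in range(n_boot):
        draws = [idx[rng.integers(0, idx.size, idx.size)] for idx in cond_idx.values()]
        f_map, _ = localization.refit(np.concatenate(draws))
        images.append(f_map)
    return images


def bootstrap_conjunction(
    image_lists: list[list[StatMap]],
    dfs: list[tuple[int, int]],
    cfg: BootstrapConfig,
    fwhm_mm: float = 9.0,
) -> StatMap:
    """Percentage-of-significant-conjunctions stability map.

    Each conjunction draws one (smoothed, p-converted) bootstrap image per
    participant, reruns the maximum-p conjunction and the BH-FDR threshold at
    ``cfg.q``, and records the binary significance mask; the output is
    100 x the mean of those masks, in [0, 100].
    """
    if any(len(imgs) == 0 for imgs in image_lists):
        raise ValueError("every participant must contribute at least one image")
    grid = _check_grids([img for imgs in image_lists for img in imgs])
    smoothed_p = [
        [map_to_p(smooth_map(img, fwhm_mm), df) for img in imgs]
        for imgs, df in zip(image_lists, dfs)
    ]
    rng = np.random.default_rng(cfg.seed)
    counts = np.zeros(grid.n_sources)
    for _ in range(cfg.n_conjunctions):
        picks = [imgs[rng.integers(len(imgs))] for imgs in smoothed_p]
        conj = conjunction_p(picks) if len(picks) > 1 else picks[0]
        counts += fdr_mask(conj, cfg.q).masked_values
    percent = 100.0 * counts / cfg.n_conjunctions
    return StatMap(grid, grid.embed(percent), "percent")
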