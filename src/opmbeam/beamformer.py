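"""Scalar max-power LCMV beamformer and voxelwise power-contrast statistics.

The linearly-constrained minimum-variance beamformer passes unit gain at a
target source while minimising output variance: w = C^-1 l / (l' C^-1 l).
The "scalar" variant first fixes a source orientation; here the orientation u
at each voxel maximises the unit-gain output power over the tangential plane,
which is the eigenvector of A = L' C^-1 L belonging to its SMALLEST
eigenvalue (output power is 1 / (u' A u)).  The data covariance is pooled
over all trials of both conditions in a single whole-trial window, with a
diagonal-loading regulariser.

Per-trial source band power is the variance of the projected trial trace;
condition differences are tested voxelwise on log-transformed powers with a
two-group t (scene minus counting; negative = power decrease) and the
equivalent one-way F = t².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forward import LeadFieldSet
from .geometry import SourceGrid
from .inference import StatMap
from .simulate import COUNTING, SCENE, EpochedData


def trial_covariances(epochs: EpochedData) -> np.ndarray:
    """(n_trials, C, C) per-trial sample covariances, trial means removed."""
    X = epochs.data - epochs.data.mean(axis=-1, keepdims=True)
    return np.einsum("tcs,tds->tcd", X, X) / epochs.n_samples


def data_covariance(epochs: EpochedData) -> np.ndarray:
    """Pooled covariance over all samples of all trials of both conditions.

    Each trial's mean is removed before pooling (whole-trial covariance
    window).  Warns when the total sample count is below the channel count,
    in which case regularisation is mandatory.
    """
    if epochs.n_trials < 2:
        raise ValueError("covariance estimation needs at least two trials")
    if epochs.n_trials * epochs.n_samples < epochs.n_channels:
        warnings.warn(
            "fewer samples than channels: covariance is rank deficient, "
            "regularisation is mandatory",
            RuntimeWarning,
        )
    return trial_covariances(epochs).mean(axis=0)


def regularize(C: np.ndarray, lam: float = 0.2) -> np.ndarray:
    """Diagonal loading: C + lam * mean(diag(C)) * I."""
    if lam < 0:
        raise ValueError("regularisation fraction must be non-negative")
    if lam == 0:
        return C.copy()
    return C + lam * np.mean(np.diag(C)) * np.eye(C.shape[0])


def _min_eigvec_2x2(A: np.ndarray) -> np.ndarray:
    """Unit eigenvectors of the smallest eigenvalue of symmetric 2x2 stacks.

    ``A`` is (..., 2, 2); the sign is fixed so the first nonzero component of
    each eigenvector is positive.
    """
    a = A[..., 0, 0]
    b = A[..., 0, 1]
    c = A[..., 1, 1]
    lam_min = 0.5 * (a + c) - np.sqrt(0.25 * (a - c) ** 2 + b**2)
    # two algebraically equivalent eigenvector forms; pick the better conditioned
    v1 = np.stack([b, lam_min - a], axis=-1)
    v2 = np.stack([lam_min - c, b], axis=-1)
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    v = np.where((n1 >= n2)[..., None], v1, v2)
    n = np.maximum(n1, n2)
    degenerate = n < 1e-300
    if np.any(degenerate):
        # b == 0 and a == c (isotropic) or A == 0: any direction is extremal
        v = v.copy()
        v[degenerate] = np.array([1.0, 0.0])
        n = np.where(degenerate, 1.0, n)
    v = v / n[..., None]
    first = v[..., 0]
    sign = np.where(np.abs(first) > 1e-12, np.sign(first), np.sign(v[..., 1]))
    sign = np.where(sign == 0, 1.0, sign)
    return v * sign[..., None]


def scalar_orientation(L: np.ndarray, C_inv: np.ndarray) -> np.ndarray:
    """Max-power source orientation(s) in the tangential basis.

    ``L`` is (C, 2) for a single source or (N, C, 2) for a stack; returns the
    unit 2-vector(s) maximising unit-gain LCMV output power, i.e. the
    smallest-eigenvalue eigenvector of A = L' C^-1 L.  A singular A yields its
    null-space direction (with a warning): that orientation has unbounded
    model power.
    """
    single = L.ndim == 2
    Ls = L[None] if single else L
    if not np.any(np.linalg.norm(Ls, axis=(1, 2)) > 0):
        raise ValueError("lead field is zero")
    A = np.einsum("nck,cd,ndj->nkj", Ls, C_inv, Ls)
    det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] ** 2
    scale = np.maximum(A[:, 0, 0], A[:, 1, 1])
    if np.any(det <= 1e-14 * scale**2):
        warnings.warn("singular orientation matrix; using its null-space direction",
                      RuntimeWarning)
    u = _min_eigvec_2x2(A)
    return u[0] if single else u


def lcmv_weights(l: np.ndarray, C_inv: np.ndarray) -> np.ndarray:
    """Unit-gain LCMV weights w = C^-1 l / (l' C^-1 l) for (C,) or (N, C) l."""
    single = l.ndim == 1
    ls = l[None] if single else l
    Cil = ls @ C_inv.T
    denom = np.einsum("nc,nc->n", ls, Cil)
    if np.any(denom <= 0):
        raise ValueError("degenerate lead field: l' C^-1 l must be positive")
    w = Cil / denom[:, None]
    return w[0] if single else w


def trial_source_power(w: np.ndarray, epochs: EpochedData) -> np.ndarray:
    """Per-trial variance of the beamformed trace over the whole epoch.

    ``w`` is (C,) or (N, C); returns (n_trials,) or (N, n_trials).
    """
    covs = trial_covariances(epochs)
    return _powers_from_covs(np.atleast_2d(w), covs) if w.ndim > 1 else \
        np.einsum("c,tcd,d->t", w, covs, w)


def _powers_from_covs(W: np.ndarray, trial_covs: np.ndarray) -> np.ndarray:
    """(N, T) projected powers w' C_t w, looping trials to bound memory."""
    n_trials = trial_covs.shape[0]
    P = np.empty((W.shape[0], n_trials))
    for t in range(n_trials):
        M = W @ trial_covs[t]
        P[:, t] = np.einsum("nc,nc->n", M, W)
    return P


@dataclass
class SourcePowerTable:
    """Per in-mask voxel x per trial band power, with condition labels."""

    powers: np.ndarray     # (n_sources, n_trials), >= 0
    labels: np.ndarray     # (n_trials,)
    grid: SourceGrid

    def to_dataframe(self) -> pd.DataFrame:
        idx = self.grid.in_mask_indices()
        n_src, n_trials = self.powers.shape
        return pd.DataFrame(
            {
                "voxel": np.repeat(np.arange(n_src), n_trials),
                "i": np.repeat(idx[:, 0], n_trials),
                "j": np.repeat(idx[:, 1], n_trials),
                "k": np.repeat(idx[:, 2], n_trials),
                "trial": np.tile(np.arange(n_trials), n_src),
                "condition": np.tile(self.labels, n_src),
                "power": self.powers.ravel(),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def power_contrast_maps(table: SourcePowerTable) -> tuple[StatMap, StatMap]:
    """Voxelwise two-group statistics on log-transformed trial powers.

    Returns (F map, t map): t is the signed two-sample statistic
    (scene - counting; negative = theta decrease) with df n1 + n2 - 2, and
    F = t² is the equivalent one-way ANOVA statistic with df (1, n1+n2-2).
    Voxels with zero within-group variance but differing means get +inf.
    """
    scene = np.flatnonzero(table.labels == SCENE)
    counting = np.flatnonzero(table.labels == COUNTING)
    n1, n2 = scene.size, counting.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both conditions need at least two trials")
    with np.errstate(divide="ignore"):
        logp = np.log(table.powers)
    x1, x2 = logp[:, scene], logp[:, counting]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    pooled = (ss1 + ss2) / (n1 + n2 - 2)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        degenerate = np.where(diff == 0, 0.0, np.sign(diff) * np.inf)
    t = np.where(se > 0, t, degenerate)
    F = t**2
    grid = table.grid
    return (
        StatMap(grid, grid.embed(F), "F"),
        StatMap(grid, grid.embed(t), "t"),
    )


def contrast_df(labels: np.ndarray) -> tuple[int, int]:
    """Degrees of freedom (1, n1 + n2 - 2) of the two-group power contrast."""
    n1 = int(np.sum(labels == SCENE))
    n2 = int(np.sum(labels == COUNTING))
    return 1, n1 + n2 - 2


@dataclass
class Localization:
    """A fitted scalar LCMV localisation for one participant.

    Holds everything needed to recompute maps under trial resampling: the
    lead fields, the per-trial covariances and the condition labels.
    """

    leadfields: LeadFieldSet
    labels: np.ndarray
    trial_covs: np.ndarray       # (T, C, C)
    lam: float
    weights: np.ndarray          # (N, C)
    orientations: np.ndarray     # (N, 2)
    powers: np.ndarray           # (N, T)

    @property
    def grid(self) -> SourceGrid:
        return self.leadfields.grid

    @property
    def df(self) -> tuple[int, int]:
        return contrast_df(self.labels)

    def power_table(self) -> SourcePowerTable:
        return SourcePowerTable(self.powers, self.labels, self.grid)

    def f_map(self) -> StatMap:
        return power_contrast_maps(self.power_table())[0]

    def t_map(self) -> StatMap:
        return power_contrast_maps(self.power_table())[1]

    def refit(self, trial_idx) -> tuple[StatMap, StatMap]:
        """Re-run covariance -> orientation -> weights -> power -> maps on a
        trial subset/multiset (used by bootstrap resampling)."""
        trial_idx = np.asarray(trial_idx, dtype=int)
        C = self.trial_covs[trial_idx].mean(axis=0)
        W, _ = _solve_weights(self.leadfields.L, C, self.lam)
        P = _powers_from_covs(W, self.trial_covs[trial_idx])
        table = SourcePowerTable(P, self.labels[trial_idx], self.grid)
        return power_contrast_maps(table)


def _solve_weights(L: np.ndarray, C: np.ndarray, lam: float):
    Creg = regularize(C, lam)
    C_inv = np.linalg.inv(Creg)
    u = scalar_orientation(L, C_inv)
    l = np.einsum("nck,nk->nc", L, u)
    W = lcmv_weights(l, C_inv)
    return W, u


def localize(
    epochs: EpochedData, leadfields: LeadFieldSet, lam: float = 0.2
) -> Localization:
    """Fit the scalar LCMV beamformer to band-passed scalp epochs.

    ``epochs`` must already be reference-regressed and band-pass filtered and
    contain scalp channels only, in the order of ``leadfields.sensors``.
    """
    if epochs.n_channels != leadfields.sensors.n_channels:
        raise ValueError("epoch channels must match the lead-field sensors")
    covs = trial_covariances(epochs)
    C = covs.mean(axis=0)
    W, u = _solve_weights(leadfields.L, C, lam)
    P = _powers_from_covs(W, covs)
    return Localization(
        leadfields=leadfields,
        labels=epochs.labels,
        trial_covs=covs,
        lam=lam,
        weights=W,
        orientations=u,
        powers=P,
    )
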