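"""End-to-end study driver: simulate, preprocess, localise, conjoin, bootstrap.

A "study" is the full multi-participant analysis: per participant, a
synthetic session is generated, trial counts are equated across conditions,
the data are baseline-corrected, reference-regressed and band-passed, and a
scalar LCMV power-contrast map is computed on a shared source grid.  The
participant F maps are then smoothed, converted to p values, combined with
the maximum-p conjunction, thresholded with BH-FDR, and reported as clusters
with peaks.  Bootstrap stability resamples each participant's trials and
repeats the conjunction on random image draws.

Every stochastic stage derives its own stream from the single study seed, so
every output is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as obio
from .beamformer import Localization, contrast_df, localize
from .forward import lead_field_matrix
from .geometry import SourceGrid, SphereHeadModel
from .inference import (
    BootstrapConfig,
    ClusterReport,
    StatMap,
    bootstrap_conjunction,
    bootstrap_images,
    clusters_and_peaks,
    conjunction_p,
    fdr_mask,
    map_to_p,
    smooth_map,
)
from .preprocess import (
    FilterSpec,
    bandpass,
    baseline_correct,
    gradiometry_r2,
    synthetic_gradiometry,
)
from .simulate import (
    CONDITIONS,
    ConditionCounts,
    EpochedData,
    GroundTruth,
    SimulationConfig,
    TrialCounts,
    apply_trial_selection,
    select_analysable_trials,
    simulate_session,
)


@dataclass
class AnalysisConfig:
    """Analysis-side parameters: filter, beamformer, grid, inference."""

    filter_low: float = 4.0
    filter_high: float = 8.0
    filter_order: int = 5
    lam: float = 0.2
    grid_n: int = 30
    grid_spacing: float = 0.003
    smoothing_fwhm_mm: float = 9.0
    q_fdr: float = 0.005
    n_boot: int = 100
    n_conjunctions: int = 500

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(self.filter_low, self.filter_high, self.filter_order)


@dataclass
class RunConfig:
    """Complete, losslessly serialisable description of one study run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        sim = d["simulation"]
        for key in ("head_center", "source_position", "source_band"):
            sim[key] = list(sim[key])
        sim["trial_counts"] = [
            {cond: list(counts) for cond, counts in
             zip(CONDITIONS, [astuple_counts(tc.scene), astuple_counts(tc.counting)])}
            for tc in self.simulation.trial_counts
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = dict(d.get("simulation", {}))
        for key in ("head_center", "source_position", "source_band"):
            if key in sim:
                sim[key] = tuple(sim[key])
        if "trial_counts" in sim:
            sim["trial_counts"] = tuple(
                TrialCounts(
                    scene=ConditionCounts(*entry["scene"]),
                    counting=ConditionCounts(*entry["counting"]),
                )
                for entry in sim["trial_counts"]
            )
        ana = dict(d.get("analysis", {}))
        return cls(
            simulation=SimulationConfig(**sim),
            analysis=AnalysisConfig(**ana),
            seed=int(d.get("seed", 0)),
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def astuple_counts(c: ConditionCounts) -> tuple[int, int, int]:
    return (c.completed, c.successful, c.artefact_removed)


def _derived_seed(seed: int, *key: int) -> int:
    """Deterministic 31-bit child seed for a named stage."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ParticipantResult:
    index: int
    epochs: EpochedData            # analysable trials, scalp, band-passed
    ground_truth: GroundTruth      # restricted to analysable trials
    localization: Localization
    f_map: StatMap
    t_map: StatMap
    f_smooth: StatMap
    p_map: StatMap
    n_analysed: int

    @property
    def df(self) -> tuple[int, int]:
        return contrast_df(self.epochs.labels)


@dataclass
class StudyResult:
    config: RunConfig
    grid: SourceGrid
    head: SphereHeadModel
    participants: list[ParticipantResult]
    conjunction_p_map: StatMap
    significance_mask: StatMap
    conjunction_stat: StatMap      # min-F across participants (max-p counterpart)
    clusters: ClusterReport
    accounting: pd.DataFrame


def study_grid(cfg: RunConfig) -> SourceGrid:
    head = cfg.simulation.head_model()
    return SourceGrid.centered_cube(head, cfg.analysis.grid_spacing, cfg.analysis.grid_n)


def prepare_participant(
    cfg: RunConfig, participant_index: int
) -> tuple[EpochedData, GroundTruth, dict]:
    """Simulate, equate trial counts and preprocess one participant.

    Returns band-passed scalp-only epochs of the analysable trials, the
    matching ground truth, and an accounting row mirroring the experiment's
    completed / successful / removed / analysed bookkeeping.
    """
    epochs, truth, row = _simulate_analysable(cfg, participant_index)
    epochs = baseline_correct(epochs)
    epochs = synthetic_gradiometry(epochs)
    epochs = bandpass(epochs, cfg.analysis.filter_spec())
    return epochs, truth, row


def localize_participant(
    epochs: EpochedData, truth: GroundTruth, cfg: RunConfig, grid: SourceGrid
) -> Localization:
    """Lead fields from the participant's (jittered) scalp array, then LCMV."""
    lfs = lead_field_matrix(truth.scalp_array, grid, truth.head)
    return localize(epochs, lfs, lam=cfg.analysis.lam)


def run_study(cfg: RunConfig) -> StudyResult:
    """The full multi-participant analysis on synthetic sessions."""
    grid = study_grid(cfg)
    head = cfg.simulation.head_model()
    participants: list[ParticipantResult] = []
    rows = []
    for p in range(cfg.simulation.n_participants):
        epochs, truth, row = prepare_participant(cfg, p)
        loc = localize_participant(epochs, truth, cfg, grid)
        f_map, t_map = loc.refit(np.arange(epochs.n_trials))
        f_smooth = smooth_map(f_map, cfg.analysis.smoothing_fwhm_mm)
        p_map = map_to_p(f_smooth, contrast_df(epochs.labels))
        participants.append(
            ParticipantResult(
                index=p,
                epochs=epochs,
                ground_truth=truth,
                localization=loc,
                f_map=f_map,
                t_map=t_map,
                f_smooth=f_smooth,
                p_map=p_map,
                n_analysed=row["analysed"],
            )
        )
        rows.append(row)
    conj = conjunction_p([pr.p_map for pr in participants])
    mask = fdr_mask(conj, cfg.analysis.q_fdr)
    min_f = np.min(
        np.stack([pr.f_smooth.masked_values for pr in participants]), axis=0
    )
    conj_stat = StatMap(grid, grid.embed(min_f), "F")
    clusters = clusters_and_peaks(mask, conj_stat)
    return StudyResult(
        config=cfg,
        grid=grid,
        head=head,
        participants=participants,
        conjunction_p_map=conj,
        significance_mask=mask,
        conjunction_stat=conj_stat,
        clusters=clusters,
        accounting=pd.DataFrame(rows),
    )


def bootstrap_stability(
    study: StudyResult,
    n_boot: int | None = None,
    n_conjunctions: int | None = None,
) -> StatMap:
    """Bootstrap-conjunction percentage map for a completed study."""
    cfg = study.config
    n_boot = n_boot if n_boot is not None else cfg.analysis.n_boot
    n_conj = n_conjunctions if n_conjunctions is not None else cfg.analysis.n_conjunctions
    image_lists = [
        bootstrap_images(
            pr.localization, n_boot, _derived_seed(cfg.seed, pr.index, 2)
        )
        for pr in study.participants
    ]
    boot_cfg = BootstrapConfig(
        n_boot_per_participant=n_boot,
        n_conjunctions=n_conj,
        q=cfg.analysis.q_fdr,
        seed=_derived_seed(cfg.seed, 9999, 3),
    )
    return bootstrap_conjunction(
        image_lists,
        [pr.df for pr in study.participants],
        boot_cfg,
        fwhm_mm=cfg.analysis.smoothing_fwhm_mm,
    )


# --------------------------------------------------------------------------
# file-based stage runners (used by the CLI)
# --------------------------------------------------------------------------

def _log(outdir: Path, stage: str, cfg: RunConfig, t0: float, **details) -> None:
    entry = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "elapsed_s": round(time.perf_counter() - t0, 3),
        **details,
    }
    with (outdir / "run_log.jsonl").open("a") as fh:
        fh.write(json.dumps(entry) + "\n")


def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    t0 = time.perf_counter()
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in range(cfg.simulation.n_participants):
        epochs, truth, row = _simulate_analysable(cfg, p)
        obio.save_session(
            outdir / f"session_p{p + 1}.h5", epochs, truth,
            config=cfg.to_dict(), seed=cfg.seed,
        )
        rows.append(row)
    accounting = pd.DataFrame(rows)
    accounting.to_csv(outdir / "trial_accounting.tsv", sep="\t", index=False)
    _log(outdir, "simulate", cfg, t0,
         trial_accounting=accounting.to_dict(orient="records"))


def _simulate_analysable(cfg: RunConfig, p: int):
    """Simulated session restricted to the equated analysable trials (raw)."""
    sim = cfg.simulation
    epochs, truth = simulate_session(sim, p, cfg.seed)
    if sim.n_trials is None:
        counts = sim.trial_counts[p]
    else:
        n = sim.n_trials
        counts = TrialCounts(ConditionCounts(n, n, 0), ConditionCounts(n, n, 0))
    n_analysed, indices = select_analysable_trials(
        counts, _derived_seed(cfg.seed, p, 1)
    )
    keep = apply_trial_selection(epochs, indices)
    row = {"participant": p + 1, "analysed": n_analysed}
    for cond in CONDITIONS:
        cc: ConditionCounts = getattr(counts, cond)
        row[f"{cond}_completed"] = cc.completed
        row[f"{cond}_successful"] = cc.successful
        row[f"{cond}_removed"] = cc.artefact_removed
    return epochs.subset_trials(keep), truth.subset_trials(keep), row


def stage_preprocess(cfg: RunConfig, outdir: Path) -> None:
    t0 = time.perf_counter()
    mean_r2 = {}
    for p in range(cfg.simulation.n_participants):
        path = outdir / f"session_p{p + 1}.h5"
        if not path.exists():
            raise FileNotFoundError(f"missing session file {path}; run simulate first")
        epochs, truth = obio.load_session(path)
        corrected = baseline_correct(epochs)
        cleaned = synthetic_gradiometry(corrected)
        r2 = gradiometry_r2(corrected, cleaned)
        obio.save_session(
            outdir / f"preproc_p{p + 1}.h5", cleaned, truth,
            config={"regression_r2_per_trial": r2.tolist()},
        )
        mean_r2[f"p{p + 1}"] = float(r2.mean())
    _log(outdir, "preprocess", cfg, t0, regression_r2_mean=mean_r2)


def stage_localize(cfg: RunConfig, outdir: Path) -> None:
    t0 = time.perf_counter()
    grid = study_grid(cfg)
    dfs = {}
    for p in range(cfg.simulation.n_participants):
        path = outdir / f"preproc_p{p + 1}.h5"
        if not path.exists():
            raise FileNotFoundError(f"missing preprocessed file {path}; run preprocess")
        epochs, truth = obio.load_session(path)
        epochs = bandpass(epochs, cfg.analysis.filter_spec())
        loc = localize_participant(epochs, truth, cfg, grid)
        f_map, t_map = loc.refit(np.arange(epochs.n_trials))
        obio.write_map(f_map, outdir / f"F_p{p + 1}.nii")
        obio.write_map(t_map, outdir / f"t_p{p + 1}.nii")
        dfs[f"p{p + 1}"] = contrast_df(epochs.labels)
    (outdir / "study.json").write_text(json.dumps({"df": dfs}))
    _log(outdir, "localize", cfg, t0, df=dfs)


def stage_conjoin(cfg: RunConfig, outdir: Path) -> None:
    t0 = time.perf_counter()
    meta = json.loads((outdir / "study.json").read_text())
    spacing_mm = cfg.analysis.grid_spacing * 1e3
    p_maps = []
    smoothed = []
    for p in range(cfg.simulation.n_participants):
        f_map = obio.read_map(outdir / f"F_p{p + 1}.nii", spacing_mm)
        sm = smooth_map(f_map, cfg.analysis.smoothing_fwhm_mm)
        smoothed.append(sm)
        p_maps.append(map_to_p(sm, tuple(meta["df"][f"p{p + 1}"])))
    conj = conjunction_p(p_maps)
    mask = fdr_mask(conj, cfg.analysis.q_fdr)
    min_f = np.min(np.stack([m.masked_values for m in smoothed]), axis=0)
    stat = StatMap(conj.grid, conj.grid.embed(min_f), "F")
    obio.write_map(conj, outdir / "conjunction_p.nii")
    obio.write_map(mask, outdir / "significance_mask.nii")
    obio.write_map(stat, outdir / "conjunction_F.nii")
    _log(outdir, "conjoin", cfg, t0, n_significant=int(mask.masked_values.sum()))


def stage_bootstrap(cfg: RunConfig, outdir: Path) -> None:
    t0 = time.perf_counter()
    grid = study_grid(cfg)
    meta = json.loads((outdir / "study.json").read_text())
    image_lists, dfs = [], []
    for p in range(cfg.simulation.n_participants):
        epochs, truth = obio.load_session(outdir / f"preproc_p{p + 1}.h5")
        epochs = bandpass(epochs, cfg.analysis.filter_spec())
        loc = localize_participant(epochs, truth, cfg, grid)
        image_lists.append(
            bootstrap_images(loc, cfg.analysis.n_boot, _derived_seed(cfg.seed, p, 2))
        )
        dfs.append(tuple(meta["df"][f"p{p + 1}"]))
    boot_cfg = BootstrapConfig(
        n_boot_per_participant=cfg.analysis.n_boot,
        n_conjunctions=cfg.analysis.n_conjunctions,
        q=cfg.analysis.q_fdr,
        seed=_derived_seed(cfg.seed, 9999, 3),
    )
    stability = bootstrap_conjunction(image_lists, dfs, boot_cfg,
                                      cfg.analysis.smoothing_fwhm_mm)
    obio.write_map(stability, outdir / "stability_percent.nii")
    _log(outdir, "bootstrap", cfg, t0,
         n_boot=cfg.analysis.n_boot, n_conjunctions=cfg.analysis.n_conjunctions)


def stage_report(cfg: RunConfig, outdir: Path) -> None:
    t0 = time.perf_counter()
    spacing_mm = cfg.analysis.grid_spacing * 1e3
    mask = obio.read_map(outdir / "significance_mask.nii", spacing_mm)
    stat = obio.read_map(outdir / "conjunction_F.nii", spacing_mm)
    report = clusters_and_peaks(mask, stat)
    report.to_tsv(outdir / "clusters.tsv")
    payload = [
        {
            "cluster": c.label,
            "n_voxels": c.n_voxels,
            "peak_mm": list(c.peak_world_mm),
            "peak_stat": c.peak_value,
        }
        for c in report.clusters
    ]
    (outdir / "clusters.json").write_text(
        json.dumps({"connectivity": 6, "tie_break": "lowest linear index",
                    "clusters": payload}, indent=2)
    )
    _log(outdir, "report", cfg, t0, n_clusters=len(report))


def stage_run_all(cfg: RunConfig, outdir: Path) -> None:
    stage_simulate(cfg, outdir)
    stage_preprocess(cfg, outdir)
    stage_localize(cfg, outdir)
    stage_conjoin(cfg, outdir)
    stage_bootstrap(cfg, outdir)
    stage_report(cfg, outdir)
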