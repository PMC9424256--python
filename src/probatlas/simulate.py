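"""Synthetic cohort generator with known ground truth.

Emulates the structure of multi-run localizer data that the pipeline
consumes: a fixed population activation landscape (a sum of 3-D Gaussian
blobs, left-lateralized via an amplitude multiplier on right-hemisphere
blobs), per-subject spatial jitter of the blob centers (the inter-individual
variability in functional-area locations that motivates probabilistic
atlases), per-subject multiplicative amplitude scaling (trait/state response
strength), and i.i.d. additive Gaussian noise per run.

Each simulated subject yields per-run "language" and "control" condition
effect maps and a pooled across-run t-map (dof = runs - 1), i.e. exactly the
inputs of the QC, atlas and marker stages.  What this generator deliberately
does not model: hemodynamics, spatially autocorrelated noise, and surface
meshes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .markers import _t_across_runs
from .atlas_build import top_fraction_binarize
from .volumes import (
    BinaryMap,
    Parcel,
    ParcelSet,
    Run,
    StatMap,
    SubjectSession,
    VolumeGrid,
    write_stat_map,
)


def sim_grid(voxel_mm: float = 12.0) -> VolumeGrid:
    """A coarse grid over the standard MNI bounding box.

    The default 12 mm resolution gives a 16 x 19 x 16 grid (4,864 voxels):
    large enough for distinct bilateral regions, small enough that cohorts
    of hundreds of subjects simulate in seconds.
    """
    lo = np.array([-90.0, -126.0, -72.0])
    hi = np.array([90.0, 90.0, 108.0])
    shape = np.floor((hi - lo) / voxel_mm).astype(int) + 1
    affine = np.diag([voxel_mm] * 3 + [1.0])
    affine[:3, 3] = lo
    return VolumeGrid(tuple(shape), affine, space=f"MNI-sim-{voxel_mm:g}mm")


@dataclass(frozen=True)
class Blob:
    """One Gaussian activation focus: center (world mm), width, peak height."""

    center: tuple[float, float, float]
    sigma_mm: float
    amplitude: float


@dataclass
class GroundTruth:
    """Population activation landscape A(v) = sum of Gaussian blobs.

    ``asymmetry`` multiplies the amplitude of every blob whose center lies
    in the right hemisphere (world x > 0); 1 means bilateral symmetry, 0
    silences the right hemisphere entirely.
    """

    grid: VolumeGrid
    blobs: list[Blob]
    asymmetry: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.asymmetry <= 1:
            raise ConfigError(f"asymmetry must be in [0,1], got {self.asymmetry}")

    def amplitude(self, offsets: Optional[np.ndarray] = None) -> np.ndarray:
        """A(v) over the grid, with optional per-blob center offsets (mm)."""
        coords = self.grid.world_coords()
        out = np.zeros(self.grid.n_voxels)
        for i, b in enumerate(self.blobs):
            c = np.asarray(b.center, dtype=float)
            if offsets is not None:
                c = c + offsets[i]
            d2 = np.sum((coords - c) ** 2, axis=1)
            amp = b.amplitude * (self.asymmetry if b.center[0] > 0 else 1.0)
            out += amp * np.exp(-d2 / (2.0 * b.sigma_mm**2))
        return out


def default_truth(
    grid: Optional[VolumeGrid] = None, asymmetry: float = 0.7
) -> GroundTruth:
    """A left-lateralized fronto-temporal-like landscape.

    Three left-hemisphere foci (inferior-frontal, anterior-temporal and
    posterior-temporal neighborhoods) with right-hemisphere homotopes scaled
    by the asymmetry factor; peak amplitude 1 in arbitrary contrast units.
    """
    grid = grid or sim_grid()
    lh = [
        Blob(center=(-48.0, 18.0, 16.0), sigma_mm=24.0, amplitude=1.0),
        Blob(center=(-52.0, -8.0, -10.0), sigma_mm=22.0, amplitude=0.9),
        Blob(center=(-54.0, -42.0, 4.0), sigma_mm=24.0, amplitude=1.0),
    ]
    rh = [Blob(center=(-b.center[0], b.center[1], b.center[2]),
               sigma_mm=b.sigma_mm, amplitude=b.amplitude) for b in lh]
    return GroundTruth(grid=grid, blobs=lh + rh, asymmetry=asymmetry)


def default_parcels(truth: GroundTruth, radius_mm: float = 30.0) -> ParcelSet:
    """Spherical parcels around each blob center, hemisphere-tagged.

    Mimics the group-level parcels within which fROIs are defined.  Radii
    are generous relative to the jitter so displaced activations stay
    inside; where spheres would overlap, each voxel goes to the nearest
    blob center, keeping parcels disjoint.
    """
    grid = truth.grid
    coords = grid.world_coords()
    centers = np.array([b.center for b in truth.blobs])
    d2 = np.sum((coords[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    nearest = d2.argmin(axis=1)
    names = {"L": 0, "R": 0}
    parcels = []
    for i, b in enumerate(truth.blobs):
        hemi = "R" if b.center[0] > 0 else "L"
        names[hemi] += 1
        parcels.append(
            Parcel(
                name=f"ROI{names[hemi]}_{hemi}",
                hemisphere=hemi,
                mask=(d2[:, i] <= radius_mm**2) & (nearest == i),
            )
        )
    return ParcelSet(domain=grid, parcels=parcels, provenance="simulated spheres")


@dataclass
class SimConfig:
    """Study conditions for a simulated cohort.

    Defaults: 200 subjects with 2 runs each (the modal localizer design),
    6 mm isotropic blob-center jitter, additive noise sd of 0.25 (a quarter
    of the peak amplitude), and log-normal amplitude scaling with
    sigma = 0.25 in log units.
    """

    n_subjects: int = 200
    n_runs: int = 2
    jitter_mm: float = 6.0
    scale_sigma: float = 0.25
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        if min(self.jitter_mm, self.scale_sigma, self.noise_sd) < 0:
            raise ConfigError("jitter_mm, scale_sigma and noise_sd must be >= 0")
        if self.seed is None:
            raise ConfigError("seed is mandatory")


def subject_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic per-subject seed so any subject reproduces in isolation."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def simulate_subject(
    truth: GroundTruth,
    cfg: SimConfig,
    seed: np.random.SeedSequence | int,
    subject: str = "sub-0001",
    session: str = "ses-1",
) -> SubjectSession:
    """Simulate one subject's multi-run session.

    Draws per-blob center offsets ~ N(0, jitter_mm^2 I) and an amplitude
    scale ~ lognormal(0, scale_sigma); each run's "language" map is the
    scaled, jittered landscape plus noise and its "control" map is noise
    around a flat zero baseline, so language - control has expectation A(v)
    times the subject scale.  A pooled across-run t-map (dof = runs - 1) is
    attached when there are >= 2 runs.
    """
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, cfg.jitter_mm, size=(len(truth.blobs), 3))
    scale = rng.lognormal(0.0, cfg.scale_sigma) if cfg.scale_sigma > 0 else 1.0
    landscape = scale * truth.amplitude(offsets)
    grid = truth.grid
    runs = []
    for r in range(1, cfg.n_runs + 1):
        lang = landscape + rng.normal(0.0, cfg.noise_sd, grid.n_voxels) \
            if cfg.noise_sd > 0 else landscape.copy()
        ctrl = rng.normal(0.0, cfg.noise_sd, grid.n_voxels) \
            if cfg.noise_sd > 0 else np.zeros(grid.n_voxels)
        runs.append(
            Run(
                index=r,
                effects={
                    "language": StatMap(subject, grid, lang, kind="effect"),
                    "control": StatMap(subject, grid, ctrl, kind="effect"),
                },
            )
        )
    sess = SubjectSession(subject=subject, session=session, runs=runs)
    if cfg.n_runs >= 2:
        contrasts = np.stack(
            [r.effects["language"].values - r.effects["control"].values for r in runs]
        )
        sess.t_map = StatMap(
            subject, grid, _t_across_runs(contrasts), kind="t", dof=cfg.n_runs - 1
        )
    return sess


def simulate_cohort(
    truth: GroundTruth, cfg: SimConfig, out_dir: Optional[str] = None
) -> list[SubjectSession]:
    """Simulate a full cohort; optionally write NIfTI maps plus a manifest.

    Subject i is seeded from (cfg.seed, i), so cohorts are bitwise
    reproducible and any subject can be regenerated alone.  When ``out_dir``
    is given, per-run condition maps and session t-maps are written as
    NIfTI with a ``manifest.csv`` (columns subject, session, run, condition,
    kind, dof, path) that :func:`load_manifest` reads back.
    """
    sessions = [
        simulate_subject(
            truth, cfg, subject_seed(cfg.seed, i),
            subject=f"sub-{i + 1:04d}", session="ses-1",
        )
        for i in range(cfg.n_subjects)
    ]
    if out_dir is not None:
        write_manifest(sessions, out_dir)
    return sessions


def write_manifest(sessions: Sequence[SubjectSession], out_dir: str) -> str:
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for s in sessions:
        for run in s.runs:
            for cond, smap in run.effects.items():
                fname = f"{s.subject}_{s.session}_run{run.index}_{cond}.nii.gz"
                write_stat_map(smap, os.path.join(out_dir, fname))
                rows.append(
                    dict(subject=s.subject, session=s.session, run=run.index,
                         condition=cond, kind="effect", dof="", path=fname)
                )
        if s.t_map is not None:
            fname = f"{s.subject}_{s.session}_tmap.nii.gz"
            write_stat_map(s.t_map, os.path.join(out_dir, fname))
            rows.append(
                dict(subject=s.subject, session=s.session, run=0, condition="",
                     kind="t", dof=s.t_map.dof, path=fname)
            )
    path = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def load_manifest(path: str) -> list[SubjectSession]:
    """Rebuild SubjectSessions from a manifest CSV written by write_manifest."""
    from .volumes import read_stat_map  # local import to keep module load light

    df = pd.read_csv(path, keep_default_na=False)
    base = os.path.dirname(os.path.abspath(path))
    sessions = []
    for (subj, sess), g in df.groupby(["subject", "session"], sort=True):
        runs: dict[int, Run] = {}
        t_map = None
        for _, row in g.iterrows():
            full = row["path"] if os.path.isabs(row["path"]) else os.path.join(base, row["path"])
            if row["kind"] == "t":
                t_map = read_stat_map(full, subject=subj, kind="t",
                                      dof=float(row["dof"]))
            else:
                idx = int(row["run"])
                run = runs.setdefault(idx, Run(index=idx, effects={}))
                run.effects[row["condition"]] = read_stat_map(
                    full, subject=subj, kind="effect"
                )
        sessions.append(
            SubjectSession(subject=subj, session=sess,
                           runs=list(runs.values()), t_map=t_map)
        )
    return sessions


def selection_probability(
    truth: GroundTruth,
    cfg: SimConfig,
    mask: BinaryMap,
    fraction: float = 0.10,
    n_mc: int = 2000,
    seed: int = 12345,
) -> np.ndarray:
    """Monte-Carlo estimate of q(v), the per-voxel selection probability.

    Runs the generative model and the top-fraction selection exactly as the
    pipeline does, over ``n_mc`` independent draws, and averages the
    resulting memberships.  The mean of q over the mask equals ``fraction``
    up to the rounding of k.
    """
    counts = np.zeros(truth.grid.n_voxels, dtype=np.int64)
    for i in range(n_mc):
        sess = simulate_subject(
            truth, cfg, np.random.SeedSequence(entropy=seed, spawn_key=(i,)),
            subject=f"mc-{i}",
        )
        stat = sess.t_map if sess.t_map is not None else StatMap(
            sess.subject, truth.grid,
            sess.runs[0].effects["language"].values
            - sess.runs[0].effects["control"].values,
            kind="contrast",
        )
        counts += top_fraction_binarize(stat, mask, fraction).membership
    return counts / n_mc
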