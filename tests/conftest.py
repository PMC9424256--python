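import numpy as np
import pytest

from probatlas import (
    BinaryMap,
    Parcel,
    ParcelSet,
    Run,
    StatMap,
    SubjectSession,
    VolumeGrid,
)


@pytest.fixture
def tiny_grid():
    """A 5x5x5 grid of 10 mm voxels centered on the origin (x = -20..20)."""
    affine = np.diag([10.0, 10.0, 10.0, 1.0])
    affine[:3, 3] = [-20.0, -20.0, -20.0]
    return VolumeGrid((5, 5, 5), affine, space="tiny")


@pytest.fixture
def line_grid():
    """A 10x1x1 grid: linear voxel index equals position, x spans -45..45."""
    affine = np.diag([10.0, 10.0, 10.0, 1.0])
    affine[:3, 3] = [-45.0, 0.0, 0.0]
    return VolumeGrid((10, 1, 1), affine, space="line")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_map(grid, values, subject="s1", kind="t", dof=None, fold=None):
    return StatMap(subject=subject, domain=grid, values=np.asarray(values, float),
                   kind=kind, dof=dof, fold=fold)


def full_mask(grid):
    return BinaryMap(domain=grid, membership=np.ones(grid.n_voxels, bool))


def uniform_session(grid, run_values, subject="s1", session="ses1"):
    """Session whose run r has uniform language value run_values[r-1], control 0."""
    runs = []
    for i, v in enumerate(run_values, start=1):
        runs.append(
            Run(
                index=i,
                effects={
                    "language": make_map(grid, np.full(grid.n_voxels, float(v)),
                                         subject=subject, kind="effect"),
                    "control": make_map(grid, np.zeros(grid.n_voxels),
                                        subject=subject, kind="effect"),
                },
            )
        )
    return SubjectSession(subject=subject, session=session, runs=runs)


def noise_session(grid, n_runs, rng, signal=None, noise_sd=1.0,
                  subject="s1", session="ses1"):
    """Session with language = signal + noise, control = noise per run."""
    sig = np.zeros(grid.n_voxels) if signal is None else np.asarray(signal, float)
    runs = []
    for i in range(1, n_runs + 1):
        lang = sig + rng.normal(0, noise_sd, grid.n_voxels)
        ctrl = rng.normal(0, noise_sd, grid.n_voxels)
        runs.append(
            Run(
                index=i,
                effects={
                    "language": make_map(grid, lang, subject=subject, kind="effect"),
                    "control": make_map(grid, ctrl, subject=subject, kind="effect"),
                },
            )
        )
    return SubjectSession(subject=subject, session=session, runs=runs)


@pytest.fixture
def halves_parcels(tiny_grid):
    """Two parcels splitting the tiny grid by hemisphere (midline excluded)."""
    x = tiny_grid.world_coords()[:, 0]
    return ParcelSet(
        domain=tiny_grid,
        parcels=[
            Parcel(name="A_L", hemisphere="L", mask=x < 0),
            Parcel(name="A_R", hemisphere="R", mask=x > 0),
        ],
    )
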