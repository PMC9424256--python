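"""Spatial data model and I/O.

Volumetric maps live on a :class:`VolumeGrid` (shape + affine); surface maps
live on a :class:`SurfaceDomain` (per-hemisphere vertex counts, stored as one
concatenated left-then-right vector).  All map values are flat 1-D float
arrays in C (row-major) scan order; "linear voxel index" throughout the
package means the position in that flattened vector, which is also the
deterministic tie-break order for voxel selection.

Coordinate conventions: voxel indices are 0-based; world coordinates are in
mm via the affine, with +x pointing to the anatomical right.  A voxel belongs
to the left hemisphere iff its world x < 0; voxels within 1e-6 mm of the
midplane belong to neither hemisphere.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import GridMismatchError, MaskError, ProbatlasError

logger = logging.getLogger(__name__)

MIDLINE_TOL_MM = 1e-6
GRID_TOL_MM = 1e-4


class VolumeGrid:
    """A 3-D voxel grid: shape, voxel->world affine, and a space label."""

    def __init__(self, shape: Sequence[int], affine: np.ndarray, space: str = ""):
        shape = tuple(int(s) for s in shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ProbatlasError(f"grid shape must be 3 positive integers, got {shape}")
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ProbatlasError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ProbatlasError("affine is not invertible")
        self.shape = shape
        self.affine = affine
        self.affine.flags.writeable = False
        self.space = space
        self._coords: Optional[np.ndarray] = None

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def compatible(self, other: "VolumeGrid", tol: float = GRID_TOL_MM) -> bool:
        return (
            isinstance(other, VolumeGrid)
            and self.shape == other.shape
            and np.allclose(self.affine, other.affine, atol=tol)
        )

    def check_compatible(self, other: "VolumeGrid") -> None:
        if not self.compatible(other):
            raise GridMismatchError(
                "incompatible grids:\n"
                f"  shape {self.shape} affine\n{self.affine}\n"
                f"  vs shape {other.shape} affine\n{other.affine}"
            )

    def world_coords(self) -> np.ndarray:
        """World-mm coordinates of every voxel center, shape (n_voxels, 3)."""
        if self._coords is None:
            ijk = np.indices(self.shape).reshape(3, -1).T  # C order
            hom = np.c_[ijk, np.ones(len(ijk))]
            self._coords = (hom @ self.affine.T)[:, :3]
        return self._coords

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest-voxel indices for world-mm points, shape (n, 3)."""
        inv = np.linalg.inv(self.affine)
        hom = np.c_[np.atleast_2d(xyz), np.ones(len(np.atleast_2d(xyz)))]
        return np.rint((hom @ inv.T)[:, :3]).astype(int)

    def __repr__(self) -> str:
        return f"VolumeGrid(shape={self.shape}, space={self.space!r})"


def mni_grid(voxel_mm: float = 2.0, space: str = "MNI-IXI549") -> VolumeGrid:
    """The common MNI bounding box (-90,-126,-72)..(90,90,108) grid.

    At the default 2 mm isotropic resolution this is the 91 x 109 x 91 grid
    (902,629 voxels) on which SPM-analysed volumetric maps are exchanged.
    """
    lo = np.array([-90.0, -126.0, -72.0])
    hi = np.array([90.0, 90.0, 108.0])
    shape = np.round((hi - lo) / voxel_mm).astype(int) + 1
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = lo
    return VolumeGrid(tuple(shape), affine, space=space)


@dataclass(frozen=True)
class SurfaceDomain:
    """Per-hemisphere vertex counts; values are stored L-then-R concatenated."""

    left: int
    right: int
    space: str = "fsaverage"

    @property
    def n_voxels(self) -> int:
        return self.left + self.right

    def compatible(self, other: "SurfaceDomain") -> bool:
        return (
            isinstance(other, SurfaceDomain)
            and self.left == other.left
            and self.right == other.right
        )

    def check_compatible(self, other: "SurfaceDomain") -> None:
        if not self.compatible(other):
            raise GridMismatchError(f"incompatible surface domains: {self} vs {other}")


Domain = Union[VolumeGrid, SurfaceDomain]

MapKind = Literal["t", "contrast", "effect"]


def _check_domains(a: Domain, b: Domain) -> None:
    if isinstance(a, VolumeGrid) != isinstance(b, VolumeGrid):
        raise GridMismatchError(f"volume/surface domain mismatch: {a} vs {b}")
    a.check_compatible(b)  # type: ignore[arg-type]


@dataclass
class StatMap:
    """One statistical image (t, contrast, or condition-effect values).

    ``values`` is a flat float64 vector over the domain; NaN marks missing.
    ``dof`` is required for p-based thresholding of t-maps.  ``fold`` labels
    data partitions such as "odd", "even" or "run2-leftout".
    """

    subject: str
    domain: Domain
    values: np.ndarray
    kind: MapKind = "t"
    dof: Optional[float] = None
    fold: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size != self.domain.n_voxels:
            raise ProbatlasError(
                f"map has {self.values.size} values for a domain of "
                f"{self.domain.n_voxels} voxels"
            )
        if self.dof is not None and self.dof <= 0:
            raise ProbatlasError(f"dof must be positive, got {self.dof}")


@dataclass
class BinaryMap:
    """Boolean membership map, e.g. a binarized subject map or a mask."""

    domain: Domain
    membership: np.ndarray
    rule: Optional["SelectionRule"] = None
    subject: str = ""

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool).ravel()
        if self.membership.size != self.domain.n_voxels:
            raise ProbatlasError("membership length does not match domain")

    @property
    def count(self) -> int:
        return int(self.membership.sum())

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.membership)


@dataclass(frozen=True)
class SelectionRule:
    """How a subject map is binarized.

    top_fraction: the top ``fraction`` of in-mask voxels by value (the
    default 0.10 gives the "top 10%" network definition).
    fixed_p: in-mask t-values exceeding the one-sided positive-tail Student-t
    critical value at ``p`` for the map's dof.
    """

    mode: Literal["top_fraction", "fixed_p"]
    fraction: Optional[float] = None
    p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode == "top_fraction":
            if self.fraction is None or self.p is not None:
                raise ProbatlasError("top_fraction rule requires fraction only")
            if not 0 < self.fraction <= 1:
                raise ProbatlasError(f"fraction must be in (0,1], got {self.fraction}")
        elif self.mode == "fixed_p":
            if self.p is None or self.fraction is not None:
                raise ProbatlasError("fixed_p rule requires p only")
            if not 0 < self.p < 1:
                raise ProbatlasError(f"p must be in (0,1), got {self.p}")
        else:
            raise ProbatlasError(f"unknown selection mode {self.mode!r}")


@dataclass
class Parcel:
    name: str
    hemisphere: Literal["L", "R"]
    mask: np.ndarray  # flat boolean

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool).ravel()
        if not self.mask.any():
            raise ProbatlasError(f"parcel {self.name!r} is empty")


@dataclass
class ParcelSet:
    """Named, hemisphere-tagged masks within which fROIs are defined."""

    domain: Domain
    parcels: list[Parcel]
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [p.name for p in self.parcels]
        if len(set(names)) != len(names):
            raise ProbatlasError("parcel names must be unique")
        for p in self.parcels:
            if p.mask.size != self.domain.n_voxels:
                raise ProbatlasError(f"parcel {p.name!r} does not match domain")

    def names(self) -> list[str]:
        return [p.name for p in self.parcels]

    def by_hemisphere(self, hemi: str) -> list[Parcel]:
        return [p for p in self.parcels if p.hemisphere == hemi]

    def __getitem__(self, name: str) -> Parcel:
        for p in self.parcels:
            if p.name == name:
                return p
        raise KeyError(name)


# ---------------------------------------------------------------------------
# sessions


@dataclass
class Run:
    """One functional run: per-condition effect maps, optional t-map."""

    index: int
    effects: dict[str, StatMap]
    t_map: Optional[StatMap] = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ProbatlasError(f"run index must be >= 1, got {self.index}")


@dataclass
class SubjectSession:
    """All first-level outputs for one subject in one scanning session.

    ``t_map`` holds the session-level statistic (e.g. the whole-session GLM
    t-map, or one pooled across runs); it is what binarization and voxel
    counting consume.
    """

    subject: str
    session: str
    runs: list[Run]
    t_map: Optional[StatMap] = None

    def __post_init__(self) -> None:
        idx = [r.index for r in self.runs]
        if len(set(idx)) != len(idx):
            raise ProbatlasError(f"duplicate run indices {idx}")
        self.runs = sorted(self.runs, key=lambda r: r.index)
        domains = [m.domain for r in self.runs for m in r.effects.values()]
        if self.t_map is not None:
            domains.append(self.t_map.domain)
        for d in domains[1:]:
            _check_domains(domains[0], d)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def domain(self) -> Domain:
        if self.runs:
            return next(iter(self.runs[0].effects.values())).domain
        assert self.t_map is not None
        return self.t_map.domain


# ---------------------------------------------------------------------------
# NIfTI / CSV I/O


def read_stat_map(
    path: str,
    expect: Optional[VolumeGrid] = None,
    subject: str = "",
    kind: MapKind = "t",
    dof: Optional[float] = None,
) -> StatMap:
    """Read a volumetric NIfTI statistical map.

    If ``expect`` is given the header grid must match it (shape equal,
    affine within 1e-4 mm) or a :class:`GridMismatchError` is raised naming
    both affines.
    """
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types
        raise ProbatlasError(f"cannot read NIfTI {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ProbatlasError(f"{path!r}: expected a 3-D volume, got shape {data.shape}")
    grid = VolumeGrid(data.shape, img.affine)
    if expect is not None:
        expect.check_compatible(grid)
        grid = expect
    return StatMap(subject=subject, domain=grid, values=data.ravel(), kind=kind, dof=dof)


def write_stat_map(smap: StatMap, path: str) -> None:
    if not isinstance(smap.domain, VolumeGrid):
        raise ProbatlasError("write_stat_map handles volume maps; use write_surface_map")
    vol = smap.values.reshape(smap.domain.shape)
    nib.save(nib.Nifti1Image(vol, smap.domain.affine), path)


def read_surface_map(
    left_path: str,
    right_path: str,
    subject: str = "",
    kind: MapKind = "t",
    dof: Optional[float] = None,
) -> StatMap:
    """Read a per-hemisphere pair of 1-D overlay NIfTI files."""
    vecs = []
    for p in (left_path, right_path):
        img = nib.load(p)
        v = np.asanyarray(img.dataobj, dtype=np.float64).ravel()
        vecs.append(v)
    domain = SurfaceDomain(left=vecs[0].size, right=vecs[1].size)
    return StatMap(
        subject=subject, domain=domain, values=np.concatenate(vecs), kind=kind, dof=dof
    )


def write_surface_map(smap: StatMap, left_path: str, right_path: str) -> None:
    if not isinstance(smap.domain, SurfaceDomain):
        raise ProbatlasError("write_surface_map requires a surface-domain map")
    nl = smap.domain.left
    for vec, p in ((smap.values[:nl], left_path), (smap.values[nl:], right_path)):
        nib.save(nib.Nifti1Image(vec.reshape(-1, 1, 1), np.eye(4)), p)


def read_mask(path: str, expect: Optional[VolumeGrid] = None) -> BinaryMap:
    smap = read_stat_map(path, expect=expect)
    return BinaryMap(domain=smap.domain, membership=smap.values > 0.5)


def write_binary_map(bmap: BinaryMap, path: str) -> None:
    if not isinstance(bmap.domain, VolumeGrid):
        raise ProbatlasError("write_binary_map handles volume maps only")
    vol = bmap.membership.reshape(bmap.domain.shape).astype(np.uint8)
    nib.save(nib.Nifti1Image(vol, bmap.domain.affine), path)


def read_parcels(
    path: str,
    names: Optional[dict[int, str]] = None,
    expect: Optional[VolumeGrid] = None,
) -> ParcelSet:
    """Read parcels from an integer label volume.

    Each positive label becomes one parcel; the hemisphere tag is inferred
    from the sign of the parcel centroid's world x (ties at x = 0 tag R).
    Default names are ``P<label>_<hemi>``.
    """
    smap = read_stat_map(path, expect=expect)
    grid = smap.domain
    assert isinstance(grid, VolumeGrid)
    labels = np.rint(smap.values).astype(int)
    parcels = []
    for lab in sorted(set(labels[labels > 0].tolist())):
        mask = labels == lab
        cx = grid.world_coords()[mask, 0].mean()
        hemi = "L" if cx < 0 else "R"
        name = names.get(lab, f"P{lab}_{hemi}") if names else f"P{lab}_{hemi}"
        parcels.append(Parcel(name=name, hemisphere=hemi, mask=mask))
    return ParcelSet(domain=grid, parcels=parcels, provenance=os.fspath(path))


def write_parcels(parcels: ParcelSet, path: str) -> None:
    """Write a ParcelSet as an integer label volume (parcels must be disjoint)."""
    grid = parcels.domain
    if not isinstance(grid, VolumeGrid):
        raise ProbatlasError("write_parcels handles volume parcel sets only")
    labels = np.zeros(grid.n_voxels, dtype=np.int16)
    for i, p in enumerate(parcels.parcels, start=1):
        if (labels[p.mask] != 0).any():
            raise ProbatlasError("overlapping parcels cannot be written as one label volume")
        labels[p.mask] = i
    nib.save(nib.Nifti1Image(labels.reshape(grid.shape), grid.affine), path)


COHORT_REQUIRED = ("subject", "session")


def load_cohort_table(path: str, check_paths: bool = True) -> pd.DataFrame:
    """Load a cohort metadata CSV; any ``*path*`` column is checked to exist."""
    df = pd.read_csv(path)
    for col in COHORT_REQUIRED:
        if col not in df.columns:
            raise ProbatlasError(f"cohort table missing required column {col!r}")
    if check_paths:
        base = os.path.dirname(os.path.abspath(path))
        for col in [c for c in df.columns if "path" in c.lower()]:
            for v in df[col].dropna():
                full = v if os.path.isabs(v) else os.path.join(base, v)
                if not os.path.exists(full):
                    raise ProbatlasError(f"cohort table references missing file {v!r}")
    return df


# ---------------------------------------------------------------------------
# masks and hemispheres


def analysis_mask(
    maps: Iterable[StatMap],
    policy: Literal["auto", "explicit"] = "auto",
    explicit: Optional[BinaryMap] = None,
) -> BinaryMap:
    """In-brain analysis mask for "across the brain" voxel selection.

    auto: voxels finite and nonzero in every map (zero-padded margins from
    resampling drop out).  explicit: validate and return the caller's mask.
    """
    maps = list(maps)
    if not maps:
        raise MaskError("no maps given")
    domain = maps[0].domain
    for m in maps[1:]:
        _check_domains(domain, m.domain)
    if policy == "explicit":
        if explicit is None:
            raise MaskError("explicit policy requires a mask")
        _check_domains(domain, explicit.domain)
        if not explicit.membership.any():
            raise MaskError("explicit mask is empty")
        return explicit
    keep = np.ones(domain.n_voxels, dtype=bool)
    for m in maps:
        keep &= np.isfinite(m.values) & (m.values != 0)
    if not keep.any():
        raise MaskError("auto analysis mask is empty")
    return BinaryMap(domain=domain, membership=keep)


def hemisphere_masks(domain: Domain) -> tuple[BinaryMap, BinaryMap, BinaryMap]:
    """(left, right, midline) masks partitioning the domain.

    Volumes: by the sign of each voxel center's world x (|x| <= 1e-6 mm is
    midline, in neither hemisphere).  Surfaces: by hemisphere block.
    """
    if isinstance(domain, SurfaceDomain):
        n = domain.n_voxels
        left = np.zeros(n, bool)
        left[: domain.left] = True
        right = ~left
        mid = np.zeros(n, bool)
    else:
        x = domain.world_coords()[:, 0]
        mid = np.abs(x) <= MIDLINE_TOL_MM
        left = (x < 0) & ~mid
        right = (x > 0) & ~mid
    return (
        BinaryMap(domain=domain, membership=left),
        BinaryMap(domain=domain, membership=right),
        BinaryMap(domain=domain, membership=mid),
    )


def mirror_mask(grid: VolumeGrid, mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Reflect a flat boolean mask through the x = 0 world plane.

    Each member voxel center maps to its nearest-voxel image under
    (x, y, z) -> (-x, y, z).  Returns (mirrored mask, n dropped outside grid).
    """
    idx = np.flatnonzero(np.asarray(mask, bool).ravel())
    xyz = grid.world_coords()[idx].copy()
    xyz[:, 0] *= -1
    ijk = grid.world_to_voxel(xyz)
    inb = np.all((ijk >= 0) & (ijk < np.array(grid.shape)), axis=1)
    dropped = int((~inb).sum())
    flat = np.ravel_multi_index(ijk[inb].T, grid.shape)
    out = np.zeros(grid.n_voxels, dtype=bool)
    out[flat] = True
    return out, dropped


def mirror_parcels(parcels: ParcelSet) -> ParcelSet:
    """Add right-hemisphere parcels mirrored from the L-tagged ones.

    Mirrors every L parcel through the midsagittal plane; members whose
    image falls outside the grid are dropped (count logged).  Names swap a
    trailing ``_L`` for ``_R`` (otherwise ``_R`` is appended).
    """
    grid = parcels.domain
    if not isinstance(grid, VolumeGrid):
        raise ProbatlasError("mirror_parcels requires a volume parcel set")
    new = list(parcels.parcels)
    for p in parcels.by_hemisphere("L"):
        mirrored, dropped = mirror_mask(grid, p.mask)
        if dropped:
            logger.warning(
                "mirror_parcels: %d voxels of %s fell outside the grid", dropped, p.name
            )
        name = p.name[:-2] + "_R" if p.name.endswith("_L") else p.name + "_R"
        new.append(Parcel(name=name, hemisphere="R", mask=mirrored))
    return ParcelSet(domain=grid, parcels=new, provenance=parcels.provenance)
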