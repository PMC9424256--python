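"""Individual-level neural markers from parcel-constrained fROIs.

For each subject and parcel we compute:

* effect size — the language>control contrast magnitude averaged over a
  subject-specific fROI, estimated with leave-one-run-out cross-validation
  so that the voxels used to define the fROI are independent of the data
  used to estimate its response (units are whatever the input effect maps
  are scaled in, e.g. % BOLD signal change);
* voxel count — the number of parcel voxels significant at an uncorrected
  one-sided threshold (default p < 0.001);
* spatial correlation — Fisher-transformed Pearson r of the contrast map
  between odd- and even-numbered runs within the parcel;
* lateralization — (LH - RH) / (LH + RH) on hemispheric voxel counts.

Per-hemisphere aggregates are unweighted means over that hemisphere's
parcels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import qc as _qc
from .atlas_build import t_critical, top_fraction_binarize
from .errors import ProbatlasError, SelectionError, SingleRunError
from .volumes import (
    BinaryMap,
    Parcel,
    ParcelSet,
    Run,
    StatMap,
    SubjectSession,
    _check_domains,
)

logger = logging.getLogger(__name__)

MARKER_NAMES = ("effect", "count", "z")


def _as_mask(parcel: Parcel | BinaryMap | np.ndarray, domain) -> np.ndarray:
    if isinstance(parcel, Parcel):
        return parcel.mask
    if isinstance(parcel, BinaryMap):
        _check_domains(domain, parcel.domain)
        return parcel.membership
    return np.asarray(parcel, dtype=bool).ravel()


def define_froi(
    smap: StatMap, parcel: Parcel | BinaryMap | np.ndarray, fraction: float = 0.10
) -> BinaryMap:
    """Top ``fraction`` of parcel voxels by statistic value (ties by index)."""
    mask = BinaryMap(domain=smap.domain, membership=_as_mask(parcel, smap.domain))
    return top_fraction_binarize(smap, mask, fraction)


def _t_across_runs(contrasts: np.ndarray) -> np.ndarray:
    """One-sample t across runs with a ranking-friendly zero-variance rule.

    Voxels with zero across-run variance get sign(mean) * inf (0 when the
    mean is 0 too) so that noise-free fixtures still rank; for inference-
    style group maps use :func:`probatlas.compare.group_t_map`, which marks
    such voxels missing instead.
    """
    n = contrasts.shape[0]
    mean = contrasts.mean(axis=0)
    sd = contrasts.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero = sd == 0
    t[zero & (mean > 0)] = np.inf
    t[zero & (mean < 0)] = -np.inf
    t[zero & (mean == 0)] = 0.0
    return t


def session_contrasts(
    session: SubjectSession, contrast: tuple[str, str] = ("language", "control")
) -> np.ndarray:
    """Per-run language-control contrast values, shape (n_runs, n_voxels)."""
    lang, ctrl = contrast
    return np.stack(
        [r.effects[lang].values - r.effects[ctrl].values for r in session.runs]
    )


def session_t_map(
    session: SubjectSession, contrast: tuple[str, str] = ("language", "control")
) -> Optional[StatMap]:
    """Session-level t statistic for binarization and voxel counting.

    Prefers an explicitly provided session t-map; otherwise pools the
    per-run contrasts into an across-run one-sample t (dof = runs - 1).
    Single-run sessions without a stored t-map yield None.
    """
    if session.t_map is not None:
        return session.t_map
    if session.n_runs < 2:
        return None
    c = session_contrasts(session, contrast)
    return StatMap(
        subject=session.subject,
        domain=session.domain,
        values=_t_across_runs(c),
        kind="t",
        dof=session.n_runs - 1,
    )


def crossval_effect_size(
    session: SubjectSession,
    parcel: Parcel | BinaryMap | np.ndarray,
    contrast: tuple[str, str] = ("language", "control"),
    fraction: float = 0.10,
) -> float:
    """Leave-one-run-out cross-validated contrast magnitude in a parcel fROI.

    For each run r, the fROI is the top ``fraction`` of parcel voxels ranked
    by the contrast statistic of all runs except r (the across-run t when
    two or more runs are held in, the held-in run's contrast otherwise);
    the fold estimate is the mean language-control contrast of run r over
    that fROI.  Fold estimates are averaged.  Fold fROIs are recomputed per
    fold, never reused.
    """
    if session.n_runs < 2:
        raise SingleRunError(
            f"effect size needs >= 2 runs; {session.subject} has {session.n_runs}"
        )
    c = session_contrasts(session, contrast)  # (runs, vox)
    domain = session.domain
    mask = _as_mask(parcel, domain)
    folds = []
    for i in range(session.n_runs):
        held_in = np.delete(np.arange(session.n_runs), i)
        if held_in.size >= 2:
            stat = _t_across_runs(c[held_in])
        else:
            stat = c[held_in[0]]
        froi = define_froi(
            StatMap(subject=session.subject, domain=domain, values=stat, kind="t"),
            mask,
            fraction,
        )
        folds.append(float(c[i][froi.membership].mean()))
    return float(np.mean(folds))


def voxel_count(
    smap: StatMap, parcel: Parcel | BinaryMap | np.ndarray, p: float = 0.001
) -> int:
    """Number of parcel voxels with t above the one-sided critical value."""
    if smap.kind != "t" or smap.dof is None:
        raise SelectionError("voxel_count needs a t-map with dof set")
    mask = _as_mask(parcel, smap.domain)
    tc = t_critical(p, smap.dof)
    vals = smap.values[mask]
    # NaN compares False; +inf (noise-free fixtures) counts as significant
    return int(np.sum(vals > tc))


@dataclass
class SpatialCorrelationMarker:
    """Odd/even split-half stability per parcel and per hemisphere."""

    parcel_r: dict[str, float]
    parcel_z: dict[str, float]
    lh_r: float
    rh_r: float
    lh_z: float
    rh_z: float


def _hemi_mean(values: dict[str, float], parcels: ParcelSet, hemi: str) -> float:
    vals = [values[p.name] for p in parcels.by_hemisphere(hemi)
            if np.isfinite(values.get(p.name, np.nan))]
    return float(np.mean(vals)) if vals else np.nan


def spatial_correlation_marker(
    session: SubjectSession,
    parcels: ParcelSet,
    contrast: tuple[str, str] = ("language", "control"),
    subset: _qc.Subset = "all",
) -> SpatialCorrelationMarker:
    """Fisher-z split-half correlation per parcel with hemisphere means.

    The hemisphere aggregate is the unweighted mean of z over that
    hemisphere's parcels; raw-r means are returned alongside.
    """
    odd, even = _qc.split_half_maps(session, contrast)
    rec = _qc.parcelwise_spatial_correlation(
        odd, even, parcels, subset=subset,
        subject=session.subject, session=session.session,
    )
    parcel_z = {k: float(_qc.fisher_z(v)) if np.isfinite(v) else np.nan
                for k, v in rec.parcel_r.items()}
    return SpatialCorrelationMarker(
        parcel_r=rec.parcel_r,
        parcel_z=parcel_z,
        lh_r=_hemi_mean(rec.parcel_r, parcels, "L"),
        rh_r=_hemi_mean(rec.parcel_r, parcels, "R"),
        lh_z=_hemi_mean(parcel_z, parcels, "L"),
        rh_z=_hemi_mean(parcel_z, parcels, "R"),
    )


def lateralization_index(lh_count: int, rh_count: int) -> float:
    """(LH - RH) / (LH + RH) on voxel counts; (0,0) -> 0 with a warning."""
    if lh_count < 0 or rh_count < 0:
        raise ProbatlasError("voxel counts must be nonnegative")
    if lh_count + rh_count == 0:
        logger.warning("lateralization undefined for zero counts; returning 0")
        return 0.0
    return (lh_count - rh_count) / (lh_count + rh_count)


@dataclass
class MarkerRecord:
    """All markers for one subject; NaN where a marker is unavailable."""

    subject: str
    session: str
    n_runs: int
    effect: dict[str, float] = field(default_factory=dict)
    count: dict[str, float] = field(default_factory=dict)
    z: dict[str, float] = field(default_factory=dict)
    lh_effect: float = np.nan
    rh_effect: float = np.nan
    lh_count: float = np.nan
    rh_count: float = np.nan
    lh_z: float = np.nan
    rh_z: float = np.nan
    lat_index: float = np.nan


def subject_markers(
    session: SubjectSession,
    parcels: ParcelSet,
    contrast: tuple[str, str] = ("language", "control"),
    fraction: float = 0.10,
    p: float = 0.001,
    subset: _qc.Subset = "all",
) -> MarkerRecord:
    """Compute every available marker for one subject session.

    Subjects with fewer than 2 runs get voxel counts only (when a session
    t-map is available); effect size and spatial correlation require the
    cross-validation / split-half structure.
    """
    rec = MarkerRecord(
        subject=session.subject, session=session.session, n_runs=session.n_runs
    )
    tmap = session_t_map(session, contrast)
    if tmap is not None:
        rec.count = {pc.name: float(voxel_count(tmap, pc, p)) for pc in parcels.parcels}
        rec.lh_count = _hemi_mean(rec.count, parcels, "L")
        rec.rh_count = _hemi_mean(rec.count, parcels, "R")
        lh_total = int(sum(rec.count[pc.name] for pc in parcels.by_hemisphere("L")))
        rh_total = int(sum(rec.count[pc.name] for pc in parcels.by_hemisphere("R")))
        rec.lat_index = lateralization_index(lh_total, rh_total)
    if session.n_runs >= 2:
        rec.effect = {
            pc.name: crossval_effect_size(session, pc, contrast, fraction)
            for pc in parcels.parcels
        }
        rec.lh_effect = _hemi_mean(rec.effect, parcels, "L")
        rec.rh_effect = _hemi_mean(rec.effect, parcels, "R")
        sc = spatial_correlation_marker(session, parcels, contrast, subset)
        rec.z = sc.parcel_z
        rec.lh_z = sc.lh_z
        rec.rh_z = sc.rh_z
    return rec


def quantile_summary(values: np.ndarray) -> dict[str, float]:
    """min / 25% / median / 75% / max with linear (type-7) interpolation."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {k: np.nan for k in ("min", "p25", "median", "p75", "max")}
    q = np.percentile(v, [0, 25, 50, 75, 100])
    return dict(zip(("min", "p25", "median", "p75", "max"), map(float, q)))


def marker_table(
    cohort: Iterable[SubjectSession],
    parcels: ParcelSet,
    contrast: tuple[str, str] = ("language", "control"),
    fraction: float = 0.10,
    p: float = 0.001,
    subset: _qc.Subset = "all",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject marker table plus a quantile summary.

    Returns (records, summary): records has one row per subject with
    ``<parcel>_<marker>`` columns, per-hemisphere aggregates and the
    lateralization index; summary has one row per hemisphere marker with
    min / 25% / median / 75% / max columns.
    """
    records = [
        subject_markers(s, parcels, contrast, fraction, p, subset) for s in cohort
    ]
    if not records:
        raise ProbatlasError("marker_table needs a nonempty cohort")
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "subject": rec.subject, "session": rec.session, "n_runs": rec.n_runs,
        }
        for pc in parcels.parcels:
            row[f"{pc.name}_effect"] = rec.effect.get(pc.name, np.nan)
            row[f"{pc.name}_count"] = rec.count.get(pc.name, np.nan)
            row[f"{pc.name}_z"] = rec.z.get(pc.name, np.nan)
        row.update(
            LH_effect=rec.lh_effect, RH_effect=rec.rh_effect,
            LH_count=rec.lh_count, RH_count=rec.rh_count,
            LH_z=rec.lh_z, RH_z=rec.rh_z, lat_index=rec.lat_index,
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    summary_rows = []
    for marker, col in (
        ("effect_size", "effect"), ("voxel_count", "count"), ("spatial_correlation", "z"),
    ):
        for hemi in ("LH", "RH"):
            qs = quantile_summary(table[f"{hemi}_{col}"].to_numpy())
            summary_rows.append({"marker": marker, "hemisphere": hemi, **qs})
    return table, pd.DataFrame(summary_rows)
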