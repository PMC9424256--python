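"""Split-half activation-stability QC and session selection.

A session's data quality is summarized by the spatial correlation, within a
set of parcels, of the language>control contrast map computed from the
odd-numbered runs against the map from the even-numbered runs.  Sessions
whose parcel-mean correlation is negative are excluded; for subjects with
several sessions the one with the highest mean correlation is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from .errors import SingleRunError
from .volumes import ParcelSet, StatMap, SubjectSession, _check_domains

logger = logging.getLogger(__name__)

#: correlations are clamped to +/-(1 - R_CLAMP) before atanh so that
#: identical halves yield a large finite Fisher z instead of infinity
R_CLAMP = 1e-7

Status = Literal["kept", "excluded_negative", "needs_review"]
Subset = Literal["all", "positive"]


@dataclass
class QCRecord:
    """Split-half QC summary for one session."""

    subject: str
    session: str
    parcel_r: dict[str, float]
    mean_r: float
    mean_z: float
    subset: Subset = "all"
    scheme: str = "odd_even"
    status: Status = "kept"
    n_parcels_used: int = 0


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilizing atanh with clamping for |r| -> 1."""
    return np.arctanh(np.clip(r, -1 + R_CLAMP, 1 - R_CLAMP))


def split_half_maps(
    session: SubjectSession,
    contrast: tuple[str, str] = ("language", "control"),
) -> tuple[StatMap, StatMap]:
    """Odd-run and even-run average contrast maps for one session.

    The per-run contrast is language - control of the run's condition effect
    maps; run numbering starts at 1, so e.g. 4 runs split into
    mean(run1, run3) vs mean(run2, run4).  Sessions with a single run cannot
    be split and raise :class:`SingleRunError`; callers should mark them
    ``needs_review`` (they require visual inspection instead).
    """
    lang, ctrl = contrast
    if session.n_runs < 2:
        raise SingleRunError(
            f"session {session.subject}/{session.session} has "
            f"{session.n_runs} run(s); split-half QC needs >= 2"
        )
    halves: dict[str, list[np.ndarray]] = {"odd": [], "even": []}
    for run in session.runs:
        diff = run.effects[lang].values - run.effects[ctrl].values
        halves["odd" if run.index % 2 == 1 else "even"].append(diff)
    if not halves["odd"] or not halves["even"]:
        raise SingleRunError(
            f"session {session.subject}/{session.session}: run indices "
            f"{[r.index for r in session.runs]} leave one half empty"
        )
    domain = session.domain
    out = []
    for fold in ("odd", "even"):
        out.append(
            StatMap(
                subject=session.subject,
                domain=domain,
                values=np.mean(halves[fold], axis=0),
                kind="contrast",
                fold=fold,
            )
        )
    return out[0], out[1]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return np.nan
    return float((xc @ yc) / denom)


def parcelwise_spatial_correlation(
    a: StatMap,
    b: StatMap,
    parcels: ParcelSet,
    subset: Subset = "all",
    subject: str = "",
    session: str = "",
) -> QCRecord:
    """Pearson r of two half-maps within each parcel, plus parcel means.

    ``subset="positive"`` restricts each parcel to voxels where both halves
    are positive.  Parcels with fewer than 2 usable voxels or zero variance
    are omitted from the means (logged).  The record's status is
    ``excluded_negative`` iff the mean raw r is negative.
    """
    _check_domains(a.domain, b.domain)
    _check_domains(a.domain, parcels.domain)
    parcel_r: dict[str, float] = {}
    usable = []
    for p in parcels.parcels:
        x = a.values[p.mask]
        y = b.values[p.mask]
        ok = np.isfinite(x) & np.isfinite(y)
        if subset == "positive":
            ok &= (x > 0) & (y > 0)
        x, y = x[ok], y[ok]
        if x.size < 2:
            logger.warning("parcel %s: <2 usable voxels, omitted", p.name)
            parcel_r[p.name] = np.nan
            continue
        r = _pearson(x, y)
        if np.isnan(r):
            logger.warning("parcel %s: zero variance, omitted", p.name)
        parcel_r[p.name] = r
        if np.isfinite(r):
            usable.append(r)
    if usable:
        mean_r = float(np.mean(usable))
        mean_z = float(np.mean(fisher_z(np.array(usable))))
    else:
        mean_r = mean_z = np.nan
    status: Status = "excluded_negative" if mean_r < 0 else "kept"
    return QCRecord(
        subject=subject or a.subject,
        session=session,
        parcel_r=parcel_r,
        mean_r=mean_r,
        mean_z=mean_z,
        subset=subset,
        status=status,
        n_parcels_used=len(usable),
    )


def qc_session(
    session: SubjectSession,
    parcels: ParcelSet,
    contrast: tuple[str, str] = ("language", "control"),
    subset: Subset = "all",
) -> QCRecord:
    """Full split-half QC for one session; single-run -> ``needs_review``."""
    try:
        odd, even = split_half_maps(session, contrast)
    except SingleRunError:
        return QCRecord(
            subject=session.subject,
            session=session.session,
            parcel_r={},
            mean_r=np.nan,
            mean_z=np.nan,
            subset=subset,
            status="needs_review",
        )
    return parcelwise_spatial_correlation(
        odd, even, parcels, subset=subset,
        subject=session.subject, session=session.session,
    )


@dataclass
class SessionSelection:
    """Result of per-subject session selection."""

    chosen: dict[str, QCRecord]
    flagged: list[str] = field(default_factory=list)  # subjects kept on review only
    excluded_subjects: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)


def select_sessions(records: Iterable[QCRecord]) -> SessionSelection:
    """Pick one session per subject.

    Negative-mean-r sessions are dropped; among the rest the session with
    the highest mean r wins (ties -> lexicographically earliest session id,
    logged).  Subjects left with only ``needs_review`` sessions pass through
    flagged; subjects left with nothing are excluded.
    """
    by_subject: dict[str, list[QCRecord]] = {}
    for rec in records:
        by_subject.setdefault(rec.subject, []).append(rec)
    out = SessionSelection(chosen={})
    for subj in sorted(by_subject):
        recs = by_subject[subj]
        negative = [r for r in recs if r.status == "excluded_negative"]
        for r in negative:
            out.log.append(
                f"excluded {subj}/{r.session}: negative mean r = {r.mean_r:.3f}"
            )
        kept = [r for r in recs if r.status == "kept"]
        review = [r for r in recs if r.status == "needs_review"]
        if kept:
            best_r = max(r.mean_r for r in kept)
            ties = sorted(r.session for r in kept if r.mean_r == best_r)
            if len(ties) > 1:
                out.log.append(
                    f"{subj}: sessions {ties} tied at r = {best_r:.3f}; "
                    f"chose {ties[0]}"
                )
            out.chosen[subj] = next(
                r for r in kept if r.session == ties[0]
            )
        elif review:
            chosen = min(review, key=lambda r: r.session)
            out.chosen[subj] = chosen
            out.flagged.append(subj)
            out.log.append(f"{subj}: only single-run session(s); kept "
                           f"{chosen.session} flagged for visual review")
        else:
            out.excluded_subjects.append(subj)
            out.log.append(f"{subj}: all sessions excluded")
    return out


def qc_table(records: Iterable[QCRecord]) -> pd.DataFrame:
    """One row per session: subject, session, r_<parcel>..., mean_r, mean_z,
    subset, scheme, status."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"subject": rec.subject, "session": rec.session}
        for name, r in rec.parcel_r.items():
            row[f"r_{name}"] = r
        row.update(
            mean_r=rec.mean_r,
            mean_z=rec.mean_z,
            subset=rec.subset,
            scheme=rec.scheme,
            status=rec.status,
        )
        rows.append(row)
    return pd.DataFrame(rows)
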