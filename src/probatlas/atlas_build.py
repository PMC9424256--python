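"""Binarization of subject maps and overlap aggregation into a probabilistic atlas.

Each subject's statistical map is reduced to a boolean membership map —
either the top fraction of in-mask voxels by value (default 10%, pooled
across both hemispheres to preserve lateralization) or the voxels exceeding
a one-sided Student-t critical value.  Averaging memberships across subjects
gives, at each voxel, the proportion of the cohort whose selected network
contains that voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MaskError, ProbatlasError, SelectionError
from .volumes import (
    BinaryMap,
    Domain,
    SelectionRule,
    StatMap,
    _check_domains,
    hemisphere_masks,
)

logger = logging.getLogger(__name__)


@dataclass
class ProbAtlas:
    """Voxelwise proportion of subjects whose binarized map includes each voxel.

    ``values`` times ``n_subjects`` is an exact integer count at every voxel.
    ``laterality`` maps subject id to the fraction of that subject's selected
    voxels falling in the left hemisphere (midline voxels excluded).
    """

    domain: Domain
    values: np.ndarray
    n_subjects: int
    rule: Optional[SelectionRule] = None
    mask: Optional[BinaryMap] = None
    laterality: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size != self.domain.n_voxels:
            raise ProbatlasError("atlas values do not match domain")


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def top_fraction_binarize(
    smap: StatMap, mask: BinaryMap, fraction: float = 0.10
) -> BinaryMap:
    """Select the top ``fraction`` of in-mask voxels by value.

    Exactly k = round-half-up(fraction * |mask|) voxels are selected; ties at
    the k-th order statistic are broken by ascending linear voxel index so
    the result is deterministic.  Selection pools both hemispheres.  Missing
    (NaN) values inside the mask are an error — the mask must exclude them.
    """
    _check_domains(smap.domain, mask.domain)
    idx = mask.indices()
    m = idx.size
    if m == 0:
        raise MaskError("empty mask")
    vals = smap.values[idx]
    if np.isnan(vals).any():
        raise SelectionError("NaN values inside the analysis mask")
    if not 0 < fraction <= 1:
        raise SelectionError(f"fraction must be in (0,1], got {fraction}")
    k = round_half_up(fraction * m)
    if k == 0:
        raise SelectionError(f"fraction {fraction} of {m} mask voxels selects 0")
    # stable sort on -values keeps equal values in ascending index order
    order = np.argsort(-vals, kind="stable")[:k]
    membership = np.zeros(smap.domain.n_voxels, dtype=bool)
    membership[idx[order]] = True
    return BinaryMap(
        domain=smap.domain,
        membership=membership,
        rule=SelectionRule(mode="top_fraction", fraction=fraction),
        subject=smap.subject,
    )


def t_critical(p: float, dof: float) -> float:
    """One-sided upper-tail Student-t critical value."""
    return float(stats.t.isf(p, dof))


def threshold_binarize(smap: StatMap, mask: BinaryMap, p: float) -> BinaryMap:
    """Select in-mask voxels with t above the one-sided critical value at ``p``.

    Unlike top-fraction selection, the result may be empty.
    """
    _check_domains(smap.domain, mask.domain)
    if smap.kind != "t" or smap.dof is None:
        raise SelectionError("fixed-p thresholding needs a t-map with dof set")
    if not 0 < p < 1:
        raise SelectionError(f"p must be in (0,1), got {p}")
    tc = t_critical(p, smap.dof)
    membership = mask.membership & np.isfinite(smap.values) & (smap.values > tc)
    return BinaryMap(
        domain=smap.domain,
        membership=membership,
        rule=SelectionRule(mode="fixed_p", p=p),
        subject=smap.subject,
    )


def binarize(smap: StatMap, mask: BinaryMap, rule: SelectionRule) -> BinaryMap:
    if rule.mode == "top_fraction":
        return top_fraction_binarize(smap, mask, rule.fraction)  # type: ignore[arg-type]
    return threshold_binarize(smap, mask, rule.p)  # type: ignore[arg-type]


def build_atlas(
    members: Sequence[BinaryMap], mask: Optional[BinaryMap] = None
) -> ProbAtlas:
    """Average subject membership maps into a probabilistic atlas."""
    members = list(members)
    if not members:
        raise ProbatlasError("build_atlas needs at least one membership map")
    domain = members[0].domain
    rule = members[0].rule
    for b in members[1:]:
        _check_domains(domain, b.domain)
        if b.rule != rule:
            raise ProbatlasError(f"mixed selection rules: {rule} vs {b.rule}")
    n = len(members)
    counts = np.zeros(domain.n_voxels, dtype=np.int64)
    for b in members:
        counts += b.membership
    left, right, _ = hemisphere_masks(domain)
    lat = {}
    for i, b in enumerate(members):
        lh = int((b.membership & left.membership).sum())
        rh = int((b.membership & right.membership).sum())
        subj = b.subject or f"subject{i:04d}"
        if lh + rh == 0:
            logger.warning("subject %s selected no hemispheric voxels", subj)
            lat[subj] = np.nan
        else:
            lat[subj] = lh / (lh + rh)
    return ProbAtlas(
        domain=domain,
        values=counts / n,
        n_subjects=n,
        rule=rule,
        mask=mask,
        laterality=pd.Series(lat, name="lh_fraction"),
    )


@dataclass
class AtlasSummary:
    n_subjects: int
    lh_min: float
    lh_max: float
    rh_min: float
    rh_max: float
    lh_fraction_mean: float
    lh_fraction_median: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": [
                    "n_subjects", "lh_min", "lh_max", "rh_min", "rh_max",
                    "lh_fraction_mean", "lh_fraction_median",
                ],
                "value": [
                    self.n_subjects, self.lh_min, self.lh_max,
                    self.rh_min, self.rh_max,
                    self.lh_fraction_mean, self.lh_fraction_median,
                ],
            }
        )


def atlas_summary(atlas: ProbAtlas, n_bins: int = 20) -> AtlasSummary:
    """Per-hemisphere value ranges and the cohort laterality distribution."""
    left, right, _ = hemisphere_masks(atlas.domain)
    lm = left.membership
    rm = right.membership
    if atlas.mask is not None:
        lm = lm & atlas.mask.membership
        rm = rm & atlas.mask.membership
    lh_vals = atlas.values[lm]
    rh_vals = atlas.values[rm]
    lat = atlas.laterality.dropna() if atlas.laterality is not None else pd.Series(dtype=float)
    counts, edges = np.histogram(atlas.values, bins=n_bins, range=(0.0, 1.0))
    return AtlasSummary(
        n_subjects=atlas.n_subjects,
        lh_min=float(lh_vals.min()) if lh_vals.size else np.nan,
        lh_max=float(lh_vals.max()) if lh_vals.size else np.nan,
        rh_min=float(rh_vals.min()) if rh_vals.size else np.nan,
        rh_max=float(rh_vals.max()) if rh_vals.size else np.nan,
        lh_fraction_mean=float(lat.mean()) if len(lat) else np.nan,
        lh_fraction_median=float(lat.median()) if len(lat) else np.nan,
        hist_edges=edges,
        hist_counts=counts,
    )


def stability_curve(
    maps: Sequence[StatMap],
    rule: SelectionRule,
    mask: BinaryMap,
    sizes: Sequence[int],
    n_boot: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlation of subsample atlases with the full-cohort atlas.

    For each n in ``sizes``, draws ``n_boot`` subsamples of n subjects
    without replacement, builds the subsample atlas and Pearson-correlates
    it with the full atlas over the mask.  Returns a table with columns
    n, mean_r, sd_r.
    """
    maps = list(maps)
    n_total = len(maps)
    if any(n > n_total or n < 1 for n in sizes):
        raise ProbatlasError(f"sizes must be in [1, {n_total}]")
    members = [binarize(m, mask, rule) for m in maps]
    stack = np.stack([b.membership[mask.membership] for b in members]).astype(np.float64)
    full = stack.mean(axis=0)
    if np.ptp(full) == 0:
        raise ProbatlasError("full-cohort atlas is constant over the mask; "
                             "stability correlation is undefined")
    rng = np.random.default_rng(seed)
    rows = []
    for n in sizes:
        rs = []
        for _ in range(n_boot):
            pick = rng.choice(n_total, size=n, replace=False)
            sub = stack[pick].mean(axis=0)
            r = np.corrcoef(sub, full)[0, 1]
            rs.append(r)
        rows.append({"n": n, "mean_r": float(np.mean(rs)),
                     "sd_r": float(np.std(rs, ddof=1)) if n_boot > 1 else np.nan})
    return pd.DataFrame(rows)
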