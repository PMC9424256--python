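"""Atlas and map comparison utilities.

Covers the validation-style analyses around atlas construction: similarity
between atlas variants (subgroups, localizer versions, t vs contrast maps),
the conventional random-effects group t-map for the same cohort, and
group-level ROIs cut from the highest-overlap atlas voxels.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .errors import ProbatlasError, SelectionError
from .atlas_build import ProbAtlas
from .volumes import BinaryMap, StatMap, _check_domains

logger = logging.getLogger(__name__)


def _masked_pearson(x: np.ndarray, y: np.ndarray, mask: Optional[np.ndarray]) -> float:
    if mask is not None:
        x, y = x[mask], y[mask]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise ProbatlasError("fewer than 2 finite voxels to correlate")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ProbatlasError("constant input; correlation undefined")
    return float((xc @ yc) / denom)


def atlas_correlation(
    a: ProbAtlas, b: ProbAtlas, mask: Optional[BinaryMap] = None
) -> float:
    """Pearson r between two atlases over the mask (or everywhere)."""
    _check_domains(a.domain, b.domain)
    m = None
    if mask is not None:
        _check_domains(a.domain, mask.domain)
        m = mask.membership
    return _masked_pearson(a.values, b.values, m)


def map_pair_correlation(
    t: StatMap, c: StatMap, mask: Optional[BinaryMap] = None
) -> float:
    """Voxelwise Pearson r between a subject's t-map and contrast map."""
    _check_domains(t.domain, c.domain)
    m = None
    if mask is not None:
        _check_domains(t.domain, mask.domain)
        m = mask.membership
    return _masked_pearson(t.values, c.values, m)


def cohort_map_pair_correlation(
    pairs: Sequence[tuple[StatMap, StatMap]], mask: Optional[BinaryMap] = None
) -> tuple[float, float, np.ndarray]:
    """Per-subject t-vs-contrast correlations; returns (mean, sd, all r)."""
    rs = np.array([map_pair_correlation(t, c, mask) for t, c in pairs])
    sd = float(rs.std(ddof=1)) if rs.size > 1 else np.nan
    return float(rs.mean()), sd, rs


def group_t_map(maps: Sequence[StatMap]) -> StatMap:
    """Voxelwise one-sample t across subjects' contrast maps (dof = n - 1).

    Voxels with zero across-subject variance are set to NaN (missing) rather
    than infinity, so downstream correlations stay well-defined; the count
    is logged.
    """
    maps = list(maps)
    n = len(maps)
    if n < 2:
        raise ProbatlasError("group t-map needs >= 2 subjects")
    domain = maps[0].domain
    for m in maps[1:]:
        _check_domains(domain, m.domain)
    stack = np.stack([m.values for m in maps])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero = sd == 0
    if zero.any():
        logger.warning("group_t_map: %d zero-variance voxels set to missing",
                       int(zero.sum()))
        t[zero] = np.nan
    return StatMap(subject="group", domain=domain, values=t, kind="t", dof=n - 1)


def atlas_group_roi(
    atlas: ProbAtlas, within: Optional[BinaryMap] = None, n_top: int = 1
) -> BinaryMap:
    """Group-level ROI: the ``n_top`` highest-overlap atlas voxels.

    Restricted to ``within`` when given; ties at the boundary are broken by
    ascending linear voxel index.
    """
    if within is not None:
        _check_domains(atlas.domain, within.domain)
        idx = within.indices()
    else:
        idx = np.flatnonzero(np.isfinite(atlas.values))
    if n_top < 1 or n_top > idx.size:
        raise SelectionError(f"n_top must be in [1, {idx.size}], got {n_top}")
    vals = atlas.values[idx]
    order = np.argsort(-vals, kind="stable")[:n_top]
    membership = np.zeros(atlas.domain.n_voxels, dtype=bool)
    membership[idx[order]] = True
    return BinaryMap(domain=atlas.domain, membership=membership, subject="group-roi")
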