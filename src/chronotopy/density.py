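"""Spatial quantification: 2D KDE contours, depth histograms, quintile ANOVA.

Operates on template-frame cell coordinates and on dorsoventral signal
profiles:

* :func:`kde2d` — axis-aligned Gaussian product-kernel density on a regular
  grid (default resolution 100 per axis), with per-axis normal-reference
  automatic bandwidth;
* :func:`hdr_levels` — highest-density-region thresholds anchored to
  fractions of sample *points* (the densest 50, 25, 15, 5 and 2.5% by
  default), giving nested contour member sets;
* :func:`depth_histogram` — the normalized y-coordinate of each cell assigned
  to one of 200 dorsoventral bins (bin 1 dorsal-most);
* :func:`compress_profile` — raw image profiles compressed to a common bin
  count (default 80) with fractional-overlap pro-rating, normalized to each
  replicate's total, with a 56-bin dorsal view and quintile partition;
* :func:`quintile_stats` — three-way ANOVA (genotype x quintile x cell-type)
  on quintile weights with Tukey HSD post-hoc tests, and
  :func:`composition_anova` — the two-way (cell-type x genotype) analogue for
  composition tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.ndimage import gaussian_filter1d
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ConfigurationError, DegenerateBandwidthError

logger = logging.getLogger(__name__)

__all__ = [
    "DensityGrid",
    "HDRLevelSet",
    "DepthProfile",
    "CompressedProfile",
    "QuintileStats",
    "DEFAULT_HDR_FRACTIONS",
    "kde2d",
    "hdr_levels",
    "depth_histogram",
    "compress_profile",
    "colocalize_profiles",
    "quintile_weights_table",
    "quintile_stats",
    "composition_anova",
]

DEFAULT_HDR_FRACTIONS = (0.50, 0.25, 0.15, 0.05, 0.025)


def _nrd_bandwidth(v: np.ndarray) -> float:
    """Normal-reference kernel SD: 1.06 * min(sd, IQR/1.34) * n^(-1/5)."""
    sd = float(np.std(v, ddof=1))
    q75, q25 = np.percentile(v, [75, 25])
    iqr = (q75 - q25) / 1.34
    spread = min(x for x in (sd, iqr) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    if spread <= 0:
        raise DegenerateBandwidthError(
            "all points identical on an axis; supply an explicit bandwidth"
        )
    return 1.06 * spread * len(v) ** (-0.2)


@dataclass(frozen=True)
class DensityGrid:
    """KDE evaluated on a regular grid; ``z[i, j]`` is the density at
    ``(x[i], y[j])``.  Retains the sample and bandwidths so densities can be
    evaluated exactly at arbitrary points."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    hx: float
    hy: float
    points: np.ndarray = field(repr=False)

    def evaluate(self, pts: np.ndarray) -> np.ndarray:
        """Exact KDE density at the given (k, 2) points."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        dx = (pts[:, 0:1] - self.points[None, :, 0]) / self.hx
        dy = (pts[:, 1:2] - self.points[None, :, 1]) / self.hy
        k = np.exp(-0.5 * (dx**2 + dy**2))
        return k.mean(axis=1) / (2.0 * np.pi * self.hx * self.hy)

    def riemann_mass(self) -> float:
        dx = self.x[1] - self.x[0]
        dy = self.y[1] - self.y[0]
        return float(self.z.sum() * dx * dy)


def kde2d(
    points: np.ndarray,
    resolution: int = 100,
    bandwidth: tuple[float, float] | None = None,
    lims: tuple[float, float, float, float] | None = None,
    pad_bandwidths: float = 4.0,
) -> DensityGrid:
    """Axis-aligned Gaussian product-kernel density on a regular grid.

    ``bandwidth`` gives the kernel SD per axis; when omitted it is chosen by
    the normal-reference rule per axis.  The default grid limits extend the
    data range by ``pad_bandwidths`` kernel SDs so the grid captures
    essentially all probability mass (Riemann sum ~ 1).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 2:
        raise ValueError("need at least two points")
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    if bandwidth is None:
        hx, hy = _nrd_bandwidth(pts[:, 0]), _nrd_bandwidth(pts[:, 1])
    else:
        hx, hy = float(bandwidth[0]), float(bandwidth[1])
        if hx <= 0 or hy <= 0:
            raise ValueError("bandwidths must be positive")
    if lims is None:
        pad_x, pad_y = pad_bandwidths * hx, pad_bandwidths * hy
        lims = (
            pts[:, 0].min() - pad_x,
            pts[:, 0].max() + pad_x,
            pts[:, 1].min() - pad_y,
            pts[:, 1].max() + pad_y,
        )
    gx = np.linspace(lims[0], lims[1], resolution)
    gy = np.linspace(lims[2], lims[3], resolution)
    kx = np.exp(-0.5 * ((gx[:, None] - pts[None, :, 0]) / hx) ** 2)
    ky = np.exp(-0.5 * ((gy[:, None] - pts[None, :, 1]) / hy) ** 2)
    z = kx @ ky.T / (len(pts) * 2.0 * np.pi * hx * hy)
    return DensityGrid(x=gx, y=gy, z=z, hx=hx, hy=hy, points=pts)


@dataclass(frozen=True)
class HDRLevelSet:
    """Highest-density thresholds per fraction, with nested member masks."""

    fractions: tuple[float, ...]
    thresholds: Mapping[float, float]
    members: Mapping[float, np.ndarray]

    def coverage(self, alpha: float) -> float:
        """Achieved member fraction for a level (>= alpha due to tie rule)."""
        mask = self.members[alpha]
        return float(mask.sum()) / len(mask)


def hdr_levels(
    points: np.ndarray,
    density_at_points: np.ndarray | None = None,
    fractions: Sequence[float] = DEFAULT_HDR_FRACTIONS,
    grid: DensityGrid | None = None,
) -> HDRLevelSet:
    """Density thresholds fitting the densest given fractions of points.

    For a fraction alpha the threshold is the density of the
    ceil(alpha * n)-th densest point (the empirical (1 - alpha) quantile);
    the member set is every point at or above it, so ties at the threshold
    are included.  Densities may be supplied, taken from a fitted
    :class:`DensityGrid`, or computed from the points themselves.
    """
    if len(fractions) == 0:
        raise ConfigurationError("fractions must not be empty")
    fr = tuple(float(a) for a in fractions)
    if any(not 0 < a <= 1 for a in fr):
        raise ConfigurationError("fractions must lie in (0, 1]")
    pts = np.asarray(points, dtype=float)
    if density_at_points is None:
        g = grid if grid is not None else kde2d(pts)
        density_at_points = g.evaluate(pts)
    dens = np.asarray(density_at_points, dtype=float)
    if len(dens) != len(pts):
        raise ValueError("one density per point required")
    order = np.sort(dens)[::-1]
    n = len(dens)
    thresholds, members = {}, {}
    for a in sorted(fr, reverse=True):
        k = int(np.ceil(a * n))
        thr = float(order[k - 1])
        thresholds[a] = thr
        members[a] = dens >= thr
    return HDRLevelSet(
        fractions=tuple(sorted(fr, reverse=True)),
        thresholds=thresholds,
        members=members,
    )


# ---------------------------------------------------------------------------
# Depth profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DepthProfile:
    """A dorsoventral binned profile; bin 1 is dorsal-most.

    For coordinate-frequency profiles, ``values`` are counts over ``n_bins``
    half-open bins spanning the template y-range dorsal-to-ventral (last bin
    closed); ``smoothed`` optionally holds a Gaussian-smoothed copy while the
    raw counts are always retained.
    """

    values: np.ndarray
    edges: np.ndarray  # descending y edges, length n_bins + 1
    smoothed: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.values)


def depth_histogram(
    y_coords: Sequence[float],
    n_bins: int = 200,
    y_range: tuple[float, float] = (2000.0, -2000.0),
    smooth: bool = False,
    smooth_bandwidth: float = 3.0,
) -> DepthProfile:
    """Assign template-frame y-coordinates to dorsoventral bins.

    ``y_range`` is (dorsal edge, ventral edge).  Bins are half-open on the
    ventral side, the last bin closed; coordinates outside the range are
    clipped into the end bins with a warning.  The bin-count total always
    equals the number of cells.  Optional smoothing applies a Gaussian kernel
    of ``smooth_bandwidth`` bins, stored alongside the raw counts.
    """
    y = np.asarray(y_coords, dtype=float)
    y_d, y_v = float(y_range[0]), float(y_range[1])
    if not y_d > y_v:
        raise ValueError("y_range must be (dorsal, ventral) with dorsal > ventral")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    outside = (y > y_d) | (y < y_v)
    if outside.any():
        logger.warning(
            "depth_histogram: %d coordinate(s) outside the template range; "
            "clipped into the end bins",
            int(outside.sum()),
        )
    width = (y_d - y_v) / n_bins
    idx = np.floor((y_d - y) / width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    values = np.bincount(idx, minlength=n_bins).astype(float)
    edges = y_d - width * np.arange(n_bins + 1)
    smoothed = (
        gaussian_filter1d(values, smooth_bandwidth, mode="nearest") if smooth else None
    )
    return DepthProfile(values=values, edges=edges, smoothed=smoothed)


@dataclass(frozen=True)
class CompressedProfile:
    """A profile compressed to a common bin count and normalized to sum 1."""

    weights: np.ndarray
    raw_sums: np.ndarray
    n_bins_common: int
    dorsal_view_bins: int = 56

    @property
    def dorsal_view(self) -> np.ndarray:
        """The dorsal-most bins (lamina VI and below excluded)."""
        return self.weights[: self.dorsal_view_bins]

    def quintiles(self) -> np.ndarray:
        """Five equal dorsoventral groups of bins, each summed."""
        if self.n_bins_common % 5 != 0:
            raise ValueError("bin count not divisible into quintiles")
        return self.weights.reshape(5, self.n_bins_common // 5).sum(axis=1)


def compress_profile(
    raw: DepthProfile | Sequence[float],
    n_bins_common: int = 80,
    dorsal_view_bins: int = 56,
) -> CompressedProfile:
    """Aggregate a raw profile into a common number of equal spans.

    Raw bins straddling a common-bin boundary are pro-rated by fractional
    overlap; aggregation is by sum, conserving the total signal, after which
    weights are normalized to sum to 1.  Raw profiles shorter than the target
    cannot be compressed (no upsampling).
    """
    values = np.asarray(
        raw.values if isinstance(raw, DepthProfile) else raw, dtype=float
    )
    n_raw = len(values)
    if n_raw < n_bins_common:
        raise ValueError(
            f"raw profile has {n_raw} bins < n_bins_common={n_bins_common}; "
            "profiles cannot be upsampled"
        )
    if (values < 0).any():
        raise ValueError("profile values must be >= 0")
    csum = np.concatenate([[0.0], np.cumsum(values)])
    edges = np.linspace(0.0, n_raw, n_bins_common + 1)
    sums = np.diff(np.interp(edges, np.arange(n_raw + 1), csum))
    total = sums.sum()
    if total <= 0:
        weights = np.zeros(n_bins_common)
    else:
        weights = sums / total
    return CompressedProfile(
        weights=weights,
        raw_sums=sums,
        n_bins_common=n_bins_common,
        dorsal_view_bins=dorsal_view_bins,
    )


def colocalize_profiles(mask_a: Sequence[float], mask_b: Sequence[float]) -> np.ndarray:
    """Elementwise product of two equal-length binary profiles.

    Emulates multiplying two thresholded marker images before profiling: the
    product is nonzero exactly where both markers are present.
    """
    a = np.asarray(mask_a, dtype=float)
    b = np.asarray(mask_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile shapes differ: {a.shape} vs {b.shape}")
    for name, m in (("mask_a", a), ("mask_b", b)):
        if not np.isin(m, (0.0, 1.0)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    return a * b


# ---------------------------------------------------------------------------
# Quintile statistics
# ---------------------------------------------------------------------------


def quintile_weights_table(
    profiles: pd.DataFrame, n_bins_common: int = 80
) -> pd.DataFrame:
    """Compress each replicate profile and tabulate its quintile weights.

    ``profiles`` is the long-format raw table (genotype, marker, replicate,
    bin, value) as produced by the profile generator; the returned long table
    has one row per (genotype, cell_type, replicate, quintile) with the
    summed weight of that quintile's bins (the marker column is treated as
    the cell-type factor).
    """
    rows = []
    for (gt, marker, rep), grp in profiles.groupby(
        ["genotype", "marker", "replicate"], sort=True
    ):
        values = grp.sort_values("bin")["value"].to_numpy()
        comp = compress_profile(values, n_bins_common=n_bins_common)
        for qi, w in enumerate(comp.quintiles(), start=1):
            rows.append(
                {
                    "genotype": gt,
                    "cell_type": marker,
                    "replicate": rep,
                    "quintile": qi,
                    "weight": w,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class QuintileStats:
    """ANOVA table plus Tukey HSD post-hoc comparisons."""

    anova: pd.DataFrame
    posthoc: pd.DataFrame


def _tukey_rows(sub: pd.DataFrame, extra: Mapping[str, object]) -> list[dict]:
    if sub["genotype"].nunique() < 2:
        return []
    res = pairwise_tukeyhsd(sub["weight"].to_numpy(), sub["genotype"].to_numpy())
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    rows = []
    for _, r in frame.iterrows():
        rows.append(
            {
                **extra,
                "group_a": r["group1"],
                "group_b": r["group2"],
                "mean_diff": float(r["meandiff"]),
                "p_adj": float(r["p-adj"]),
            }
        )
    return rows


def quintile_stats(table: pd.DataFrame) -> QuintileStats:
    """Three-way ANOVA (genotype x quintile x cell-type) on quintile weights.

    ``table`` is the long format from :func:`quintile_weights_table` (or
    equivalent).  All interactions are included; when only one cell type is
    present that factor is dropped (two-way ANOVA) with a warning.  Post-hoc
    Tukey HSD comparisons between genotypes are run per dorsoventral quintile
    (and per cell type when several are present).
    """
    required = {"genotype", "cell_type", "replicate", "quintile", "weight"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"quintile table lacks columns: {sorted(missing)}")
    counts = table.groupby(["genotype", "cell_type"])["replicate"].nunique()
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates per genotype x cell-type group")

    n_types = table["cell_type"].nunique()
    if n_types > 1:
        formula = "weight ~ C(genotype) * C(quintile) * C(cell_type)"
    else:
        logger.warning(
            "quintile_stats: single cell type; dropping the cell-type factor"
        )
        formula = "weight ~ C(genotype) * C(quintile)"
    model = smf.ols(formula, data=table).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    posthoc_rows: list[dict] = []
    group_cols = ["quintile"] if n_types == 1 else ["quintile", "cell_type"]
    for key, sub in table.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        extra = dict(zip(group_cols, key))
        posthoc_rows.extend(_tukey_rows(sub, extra))
    return QuintileStats(anova=anova, posthoc=pd.DataFrame(posthoc_rows))


def composition_anova(table: pd.DataFrame) -> QuintileStats:
    """Two-way ANOVA (cell-type x genotype) on per-replicate frequencies.

    ``table`` columns: genotype, cell_type, replicate, frequency (e.g.
    section-count-normalized contingency values).  Tukey HSD comparisons
    between genotypes are run for each cell type.
    """
    required = {"genotype", "cell_type", "replicate", "frequency"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"composition table lacks columns: {sorted(missing)}")
    model = smf.ols("frequency ~ C(cell_type) * C(genotype)", data=table).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    rows: list[dict] = []
    for ct, sub in table.groupby("cell_type", sort=True):
        sub = sub.rename(columns={"frequency": "weight"})
        rows.extend(_tukey_rows(sub, {"cell_type": ct}))
    return QuintileStats(anova=anova, posthoc=pd.DataFrame(rows))
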