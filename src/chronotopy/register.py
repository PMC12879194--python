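"""Landmark-based registration of spinal cord sections onto an idealized template.

Sections carry ten manually placed anatomical anchors: the dorsal-most extent
of each dorsal horn, the lateral-most extent of each dorsal horn, the base of
the dorsal columns, the lateral-most and ventral-most extents of each ventral
horn, and the midline dorsoventral junction (where the ependymal/progenitor
zone diverges dorsally but is adhered ventrally).  Registration proceeds in
two steps:

1. ``rotate_to_midline`` — a rigid motion placing the dorsoventral junction at
   the origin with the dorsal-column base straight above it, so both midline
   anchors share an x-coordinate and the midline is the y-axis;
2. ``warp_to_template`` — a per-hemisection monotone piecewise-linear stretch
   of y through the anchor levels, and a per-hemisection x-scaling blended
   linearly in y between the dorsal-horn-lateral and ventral-horn-lateral
   scales, pinning every anchored level onto the idealized template (dorsal
   and ventral extremes at y = +/-2000, lateral dorsal-horn extremes at
   x = +/-2000 arbitrary units).

``normalize_section`` composes the two.  The module also builds mirrored
genotype overlays (reference on x < 0, alternate on x > 0) and ratio-matched
per-type downsampling of a reference cell table.

Cell tables are plain :class:`pandas.DataFrame` objects with the columns in
:data:`CELL_COLUMNS`; the coordinate frame ("raw", "rotated" or "template")
is tracked in ``df.attrs["frame"]``.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    FrameMismatchError,
    LandmarkOrderError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnchorRole",
    "SectionLandmarks",
    "TemplateSpec",
    "CELL_COLUMNS",
    "make_cell_table",
    "get_frame",
    "set_frame",
    "rotate_to_midline",
    "warp_to_template",
    "normalize_section",
    "mirror_overlay",
    "downsample_matched",
]


class AnchorRole(str, enum.Enum):
    """The ten anatomical anchor roles of one section."""

    DH_dorsal_L = "DH_dorsal_L"
    DH_dorsal_R = "DH_dorsal_R"
    DH_lateral_L = "DH_lateral_L"
    DH_lateral_R = "DH_lateral_R"
    DC_base = "DC_base"
    VH_lateral_L = "VH_lateral_L"
    VH_lateral_R = "VH_lateral_R"
    VH_ventral_L = "VH_ventral_L"
    VH_ventral_R = "VH_ventral_R"
    DV_junction = "DV_junction"


#: Anchors that lie on the midline (x = 0 in the template frame).
MIDLINE_ROLES = (AnchorRole.DC_base, AnchorRole.DV_junction)

CELL_COLUMNS = [
    "section_id",
    "x",
    "y",
    "type_label",
    "family_label",
    "edu_flag",
    "genotype",
    "segment_group",
]

_FRAMES = ("raw", "rotated", "template")


def make_cell_table(
    x: Iterable[float],
    y: Iterable[float],
    *,
    section_id: str = "s1",
    type_label: object = "unknown",
    family_label: object = "unknown",
    edu_flag: object = False,
    genotype: object = "wt",
    segment_group: object = "cervical",
    frame: str = "raw",
) -> pd.DataFrame:
    """Assemble a cell table from coordinates plus (scalar or per-cell) labels."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("cell coordinates must be finite")
    df = pd.DataFrame(
        {
            "section_id": section_id,
            "x": x,
            "y": y,
            "type_label": type_label,
            "family_label": family_label,
            "edu_flag": edu_flag,
            "genotype": genotype,
            "segment_group": segment_group,
        }
    )
    return set_frame(df, frame)


def get_frame(cells: pd.DataFrame) -> str:
    return cells.attrs.get("frame", "raw")


def set_frame(cells: pd.DataFrame, frame: str) -> pd.DataFrame:
    if frame not in _FRAMES:
        raise ValueError(f"unknown coordinate frame {frame!r}; expected one of {_FRAMES}")
    cells.attrs["frame"] = frame
    return cells


def _require_frame(cells: pd.DataFrame, frame: str, op: str) -> None:
    got = get_frame(cells)
    if got != frame:
        raise FrameMismatchError(f"{op} expects cells in the {frame!r} frame, got {got!r}")


@dataclass(frozen=True)
class SectionLandmarks:
    """The ten named anchor points of one section, in one coordinate frame."""

    section_id: str
    anchors: Mapping[AnchorRole, tuple[float, float]]
    frame: str = "raw"

    def __post_init__(self) -> None:
        roles = set(self.anchors)
        expected = set(AnchorRole)
        if roles != expected:
            missing = sorted(r.value for r in expected - roles)
            extra = sorted(str(r) for r in roles - expected)
            raise ValueError(
                f"landmark set must contain exactly the 10 anchor roles; "
                f"missing={missing} unexpected={extra}"
            )
        for role, (px, py) in self.anchors.items():
            if not (math.isfinite(px) and math.isfinite(py)):
                raise ValueError(f"anchor {role.value} has non-finite coordinates")
        dc = self.anchors[AnchorRole.DC_base]
        dv = self.anchors[AnchorRole.DV_junction]
        if dc == dv:
            raise ValueError("DC_base and DV_junction must be distinct points")

    def xy(self, role: AnchorRole) -> tuple[float, float]:
        return tuple(self.anchors[role])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"section_id": self.section_id, "role": role.value, "x": px, "y": py}
            for role, (px, py) in sorted(self.anchors.items(), key=lambda kv: kv[0].value)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame: str = "raw") -> "SectionLandmarks":
        """Read a (section_id, role, x, y) table for a single section."""
        sections = df["section_id"].unique()
        if len(sections) != 1:
            raise ValueError("from_frame expects a single section")
        counts = df["role"].value_counts()
        dup = counts[counts > 1]
        if not dup.empty:
            raise ValueError(f"duplicated anchor roles: {sorted(dup.index)}")
        anchors = {
            AnchorRole(row.role): (float(row.x), float(row.y)) for row in df.itertuples()
        }
        return cls(section_id=str(sections[0]), anchors=anchors, frame=frame)


# Per-segment-group overrides of the intermediate template levels.  The
# extreme levels (+/-2000) are fixed by convention; the intermediate ones are
# arbitrary and tuned per segmental group to fit an ideal cord diagram.
_SEGMENT_OVERRIDES: dict[str, dict[str, float]] = {
    "cervical": {},
    "brachial": {"y_dc": 1300.0, "x_vlat": 1700.0},
    "thoracic": {"y_dc": 1100.0, "y_lat": 700.0, "x_vlat": 1400.0},
    "lumbar": {"y_dc": 1250.0, "x_vlat": 1750.0},
}


@dataclass(frozen=True)
class TemplateSpec:
    """Idealized template positions for the anchored levels.

    Units are the template's arbitrary units of distance.  The dorsal/ventral
    extremes and the lateral dorsal-horn extremes are fixed at +/-2000; the
    intermediate levels (dorsal-column base, lateral dorsal horn, lateral
    ventral horn) are arbitrary and may be overridden per segment group.
    """

    y_dorsal: float = 2000.0
    y_ventral: float = -2000.0
    x_lateral: float = 2000.0
    y_dc: float = 1200.0
    y_lat: float = 800.0
    y_vlat: float = -800.0
    x_vlat: float = 1600.0
    #: template x of the dorsal-most DH anchors and ventral-most VH anchors
    #: (used only when synthesizing ideal sections; the warp does not pin them).
    x_dorsal: float = 900.0
    x_ventral: float = 700.0

    def __post_init__(self) -> None:
        if not (self.y_dorsal > self.y_dc > self.y_lat > 0 > self.y_vlat > self.y_ventral):
            raise ValueError(
                "template y-levels must satisfy Y_D > Y_DC > Y_LAT > 0 > Y_VLAT > Y_V"
            )
        if not (self.x_lateral > 0 and self.x_vlat > 0):
            raise ValueError("lateral template x-positions must be positive")

    @classmethod
    def for_segment(cls, segment_group: str = "cervical") -> "TemplateSpec":
        over = _SEGMENT_OVERRIDES.get(segment_group, {})
        return cls(**over)

    def anchor_positions(self) -> dict[AnchorRole, tuple[float, float]]:
        """Canonical template-frame positions of all ten anchors."""
        return {
            AnchorRole.DH_dorsal_L: (-self.x_dorsal, self.y_dorsal),
            AnchorRole.DH_dorsal_R: (self.x_dorsal, self.y_dorsal),
            AnchorRole.DH_lateral_L: (-self.x_lateral, self.y_lat),
            AnchorRole.DH_lateral_R: (self.x_lateral, self.y_lat),
            AnchorRole.DC_base: (0.0, self.y_dc),
            AnchorRole.VH_lateral_L: (-self.x_vlat, self.y_vlat),
            AnchorRole.VH_lateral_R: (self.x_vlat, self.y_vlat),
            AnchorRole.VH_ventral_L: (-self.x_ventral, self.y_ventral),
            AnchorRole.VH_ventral_R: (self.x_ventral, self.y_ventral),
            AnchorRole.DV_junction: (0.0, 0.0),
        }


def rotate_to_midline(
    cells: pd.DataFrame, anchors: SectionLandmarks
) -> tuple[pd.DataFrame, SectionLandmarks]:
    """Rigidly move a section so the midline anchors share x = 0.

    The dorsoventral junction is translated to the origin and all coordinates
    are rotated so the dorsal-column base lies on the positive y-axis; of the
    two solutions that verticalize the midline this uniquely puts dorsal up.
    The same transform is applied to cells and anchors.
    """
    _require_frame(cells, "raw", "rotate_to_midline")
    dvx, dvy = anchors.xy(AnchorRole.DV_junction)
    dcx, dcy = anchors.xy(AnchorRole.DC_base)
    dx, dy = dcx - dvx, dcy - dvy
    r = math.hypot(dx, dy)
    if r < 1e-12:
        raise DegenerateGeometryError(
            "DC_base and DV_junction coincide; the midline rotation is undefined"
        )
    cos_phi, sin_phi = dy / r, dx / r  # rotate (dx, dy) onto (0, r)

    def _apply(px: np.ndarray, py: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tx, ty = px - dvx, py - dvy
        return cos_phi * tx - sin_phi * ty, sin_phi * tx + cos_phi * ty

    out = cells.copy()
    out["x"], out["y"] = _apply(cells["x"].to_numpy(float), cells["y"].to_numpy(float))
    set_frame(out, "rotated")

    new_anchors = {}
    for role, (px, py) in anchors.anchors.items():
        ax, ay = _apply(np.array([px]), np.array([py]))
        new_anchors[role] = (float(ax[0]), float(ay[0]))
    # snap the midline anchors onto the axis exactly (rotation rounding only)
    new_anchors[AnchorRole.DV_junction] = (0.0, 0.0)
    new_anchors[AnchorRole.DC_base] = (0.0, new_anchors[AnchorRole.DC_base][1])
    rotated = SectionLandmarks(anchors.section_id, new_anchors, frame="rotated")
    return out, rotated


def _interp_extrap(v: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation through (xs, ys), linearly extended."""
    v = np.asarray(v, dtype=float)
    out = np.interp(v, xs, ys)
    lo, hi = v < xs[0], v > xs[-1]
    if lo.any():
        s = (ys[1] - ys[0]) / (xs[1] - xs[0])
        out[lo] = ys[0] + (v[lo] - xs[0]) * s
    if hi.any():
        s = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        out[hi] = ys[-1] + (v[hi] - xs[-1]) * s
    return out


def _side_roles(side: str) -> dict[str, AnchorRole]:
    return {
        "dh_dorsal": AnchorRole[f"DH_dorsal_{side}"],
        "dh_lateral": AnchorRole[f"DH_lateral_{side}"],
        "vh_lateral": AnchorRole[f"VH_lateral_{side}"],
        "vh_ventral": AnchorRole[f"VH_ventral_{side}"],
    }


@dataclass(frozen=True)
class _HemisectionWarp:
    """One hemisection's y-control pairs and blended x-scale parameters."""

    y_src: np.ndarray  # strictly increasing rotated-frame control y levels
    y_dst: np.ndarray  # matching template levels
    s_dh: float  # x-scale at the DH-lateral level
    s_vh: float  # x-scale at the VH-lateral level
    y_dh: float  # rotated y of the DH-lateral anchor
    y_vh: float  # rotated y of the VH-lateral anchor

    def warp_y(self, y: np.ndarray) -> np.ndarray:
        return _interp_extrap(y, self.y_src, self.y_dst)

    def x_scale(self, y: np.ndarray) -> np.ndarray:
        t = np.clip((np.asarray(y, float) - self.y_vh) / (self.y_dh - self.y_vh), 0.0, 1.0)
        return self.s_vh + t * (self.s_dh - self.s_vh)


def hemisection_warp(
    anchors: SectionLandmarks, spec: TemplateSpec, side: str
) -> _HemisectionWarp:
    """Build one hemisection's warp from rotated-frame anchors.

    Control levels run ventral to dorsal: VH ventral extreme, VH lateral
    extreme, dorsoventral junction, DH lateral extreme, DC base, DH dorsal
    extreme.  Their rotated y-coordinates must be strictly increasing in that
    order or the landmarks are anatomically inconsistent.
    """
    roles = _side_roles(side)
    order = [
        (roles["vh_ventral"], spec.y_ventral),
        (roles["vh_lateral"], spec.y_vlat),
        (AnchorRole.DV_junction, 0.0),
        (roles["dh_lateral"], spec.y_lat),
        (AnchorRole.DC_base, spec.y_dc),
        (roles["dh_dorsal"], spec.y_dorsal),
    ]
    y_src = np.array([anchors.xy(role)[1] for role, _ in order], dtype=float)
    y_dst = np.array([target for _, target in order], dtype=float)
    if not np.all(np.diff(y_src) > 0):
        bad = [
            f"{order[i][0].value} (y={y_src[i]:.6g}) !< {order[i + 1][0].value} (y={y_src[i + 1]:.6g})"
            for i in range(len(y_src) - 1)
            if not y_src[i] < y_src[i + 1]
        ]
        raise LandmarkOrderError(
            "anchor y-levels are not strictly ordered ventral-to-dorsal: " + "; ".join(bad)
        )
    sign = -1.0 if side == "L" else 1.0
    x_dh = anchors.xy(roles["dh_lateral"])[0]
    x_vh = anchors.xy(roles["vh_lateral"])[0]
    if sign * x_dh <= 0 or sign * x_vh <= 0:
        raise LandmarkOrderError(
            f"lateral anchors of hemisection {side} must lie on the {side} side of the midline"
        )
    return _HemisectionWarp(
        y_src=y_src,
        y_dst=y_dst,
        s_dh=(sign * spec.x_lateral) / x_dh,
        s_vh=(sign * spec.x_vlat) / x_vh,
        y_dh=anchors.xy(roles["dh_lateral"])[1],
        y_vh=anchors.xy(roles["vh_lateral"])[1],
    )


def _warp_points(
    x: np.ndarray, y: np.ndarray, wl: _HemisectionWarp, wr: _HemisectionWarp
) -> tuple[np.ndarray, np.ndarray]:
    """Warp points, assigning hemisections by the sign of rotated x.

    Points exactly on the midline take the mean of the left/right y-warps
    (their x stays 0).
    """
    yl, yr = wl.warp_y(y), wr.warp_y(y)
    xl = wl.x_scale(y) * x
    xr = wr.x_scale(y) * x
    left = x < 0
    mid = x == 0
    new_y = np.where(left, yl, yr)
    new_y[mid] = 0.5 * (yl[mid] + yr[mid])
    new_x = np.where(left, xl, xr)
    new_x[mid] = 0.0
    return new_x, new_y


def warp_to_template(
    cells: pd.DataFrame, anchors: SectionLandmarks, spec: TemplateSpec | None = None
) -> tuple[pd.DataFrame, SectionLandmarks]:
    """Stretch a rotated section onto the idealized template.

    y is mapped per hemisection by the monotone piecewise-linear function
    through the six anchored levels; x is scaled per hemisection, blending
    linearly in y between the DH-lateral and VH-lateral scales (clamped to the
    nearer scale outside that span).
    """
    _require_frame(cells, "rotated", "warp_to_template")
    if anchors.frame != "rotated":
        raise FrameMismatchError("warp_to_template expects rotated-frame anchors")
    spec = spec or TemplateSpec()
    wl = hemisection_warp(anchors, spec, "L")
    wr = hemisection_warp(anchors, spec, "R")

    out = cells.copy()
    out["x"], out["y"] = _warp_points(
        cells["x"].to_numpy(float), cells["y"].to_numpy(float), wl, wr
    )
    set_frame(out, "template")

    new_anchors = {}
    for role, (px, py) in anchors.anchors.items():
        ax, ay = _warp_points(np.array([px]), np.array([py]), wl, wr)
        new_anchors[role] = (float(ax[0]), float(ay[0]))
    warped = SectionLandmarks(anchors.section_id, new_anchors, frame="template")
    return out, warped


def normalize_section(
    cells: pd.DataFrame, anchors: SectionLandmarks, spec: TemplateSpec | None = None
) -> tuple[pd.DataFrame, SectionLandmarks]:
    """Rotate to the midline, then warp onto the template (full normalization)."""
    rotated_cells, rotated_anchors = rotate_to_midline(cells, anchors)
    return warp_to_template(rotated_cells, rotated_anchors, spec)


def mirror_overlay(ref_cells: pd.DataFrame, alt_cells: pd.DataFrame) -> pd.DataFrame:
    """Overlay two template-frame cell tables on opposite hemisections.

    Reference cells are reflected to x <= 0, alternate cells to x >= 0;
    y-coordinates are untouched.  The output keeps every input column and adds
    an ``overlay_side`` provenance column ("ref"/"alt").
    """
    for name, df in (("ref", ref_cells), ("alt", alt_cells)):
        if get_frame(df) != "template":
            raise FrameMismatchError(
                f"mirror_overlay expects template-frame cells; {name} table is "
                f"in frame {get_frame(df)!r}"
            )
    ref = ref_cells.copy()
    ref["x"] = -ref["x"].abs()
    ref["overlay_side"] = "ref"
    alt = alt_cells.copy()
    alt["x"] = alt["x"].abs()
    alt["overlay_side"] = "alt"
    out = pd.concat([ref, alt], ignore_index=True)
    return set_frame(out, "template")


def downsample_matched(
    ref_cells: pd.DataFrame, alt_total: int, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Downsample a reference table to match an alternate group's total count.

    Each cell type's count is multiplied by r = alt_total / ref_total, rounded
    half-to-even, and that many cells are drawn without replacement within the
    type.  If r > 1 the table cannot be upsampled and is returned unchanged
    (with a warning).
    """
    if alt_total <= 0:
        raise ValueError("alt_total must be positive")
    ref_total = len(ref_cells)
    if ref_total == 0:
        raise ValueError("reference table is empty")
    r = alt_total / ref_total
    if r > 1:
        logger.warning(
            "downsample_matched: ratio %.3f > 1 (alt_total=%d, ref_total=%d); "
            "cannot upsample, returning the reference table unchanged",
            r,
            alt_total,
            ref_total,
        )
        out = ref_cells.copy()
        return set_frame(out, get_frame(ref_cells))
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    kept_indices: list[np.ndarray] = []
    for _, group in ref_cells.groupby("type_label", sort=True):
        k = int(np.rint(r * len(group)))  # rint rounds half to even
        if k > 0:
            chosen = rng.choice(group.index.to_numpy(), size=k, replace=False)
            kept_indices.append(np.sort(chosen))
    if kept_indices:
        idx = np.concatenate(kept_indices)
    else:
        idx = np.array([], dtype=int)
    out = ref_cells.loc[np.sort(idx)].reset_index(drop=True)
    return set_frame(out, get_frame(ref_cells))
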