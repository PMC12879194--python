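"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the data the pipeline consumes:

* :func:`make_section` — a bilaterally symmetric section of laminar cell
  placements, distorted off the idealized template by an invertible
  piecewise-linear warp, rigidly rotated/translated, and jittered; the ten
  anchor landmarks are carried through the same transform, so registration
  can be tested against the known canonical coordinates.
* :func:`make_birth_counts` — litter x embryo x pulse-timepoint EdU
  co-labeling count tables from overlapping Gaussian birth waves.
* :func:`make_composition_series` — smooth cell-type proportion curves over
  quarter-day timepoints, multinomially sampled.
* :func:`make_depth_profiles` — dorsoventral binned signal profiles with
  per-genotype peak placement (e.g. a laminar shift in a mutant).

All generators are pure functions of their configuration (which includes the
seed); randomness flows from one ``numpy`` ``SeedSequence`` with spawned
sub-streams per litter/section, so outputs are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .register import (
    AnchorRole,
    SectionLandmarks,
    TemplateSpec,
    hemisection_warp,
    make_cell_table,
    set_frame,
)
from .tempsim import CompositionSeries

__all__ = [
    "FamilyLayout",
    "SectionSimConfig",
    "BirthWave",
    "BirthSimConfig",
    "TypeWave",
    "CompositionSimConfig",
    "ProfilePeak",
    "ProfileSimConfig",
    "make_section",
    "make_birth_counts",
    "make_composition_series",
    "make_depth_profiles",
    "DEFAULT_FAMILY_LAYOUT",
    "DEFAULT_BIRTH_WAVES",
]


@dataclass(frozen=True)
class FamilyLayout:
    """Template-frame laminar placement of one cell family.

    ``mean_y``/``sd_y`` position the family's dorsoventral band and
    ``mean_abs_x``/``sd_x`` its mediolateral spread (mirrored across the
    midline); ``weight`` is the family's share of cells.
    """

    mean_y: float
    sd_y: float
    mean_abs_x: float
    sd_x: float
    weight: float = 1.0


#: Six laminar bands layered dorsal to ventral within the dorsal horn,
#: mimicking temporal-cohort settlement (template units).
DEFAULT_FAMILY_LAYOUT: dict[str, FamilyLayout] = {
    "fam1": FamilyLayout(1600.0, 140.0, 900.0, 260.0),
    "fam2": FamilyLayout(1330.0, 140.0, 950.0, 260.0),
    "fam3": FamilyLayout(1060.0, 140.0, 1000.0, 260.0),
    "fam4": FamilyLayout(790.0, 140.0, 950.0, 260.0),
    "fam5": FamilyLayout(520.0, 140.0, 900.0, 260.0),
    "fam6": FamilyLayout(250.0, 140.0, 850.0, 260.0),
}


@dataclass(frozen=True)
class SectionSimConfig:
    n_cells: int = 600
    rotation_deg: float = 15.0
    jitter_sd: float = 0.0
    family_layout: Mapping[str, FamilyLayout] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_LAYOUT)
    )
    #: magnitude of the random anatomical distortion between the template and
    #: the "raw" section (0 = raw geometry identical to the template).
    warp_strength: float = 0.15
    translation: tuple[float, float] = (0.0, 0.0)
    section_id: str = "sim1"
    segment_group: str = "cervical"
    genotype: str = "wt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ConfigurationError("n_cells must be positive")
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter_sd must be >= 0")
        if not self.family_layout:
            raise ConfigurationError("family_layout must not be empty")
        for name, lay in self.family_layout.items():
            if lay.sd_y <= 0 or lay.sd_x <= 0:
                raise ConfigurationError(f"family {name!r} has sd <= 0")
            if lay.weight <= 0:
                raise ConfigurationError(f"family {name!r} has non-positive weight")
        if not 0 <= self.warp_strength < 0.4:
            raise ConfigurationError("warp_strength must lie in [0, 0.4)")


def _distortion_factors(
    rng: np.random.Generator, strength: float
) -> dict[str, float]:
    """Per-control random scale factors defining the template->raw distortion.

    The dorsal-column-base level is on the midline and shared by both sides;
    every other y level and both lateral x extents get an independent factor
    per hemisection.
    """

    def f() -> float:
        return float(1.0 + strength * rng.uniform(-1.0, 1.0))

    factors = {"y_dc": f()}
    for side in ("L", "R"):
        for key in ("y_ventral", "y_vlat", "y_lat", "y_dorsal", "x_dh", "x_vh"):
            factors[f"{key}_{side}"] = f()
    return factors


def make_section(
    cfg: SectionSimConfig, spec: TemplateSpec | None = None
) -> tuple[pd.DataFrame, SectionLandmarks, pd.DataFrame]:
    """Simulate one section: raw cells, raw landmarks, and the canonical truth.

    Cells are placed in the template frame per the family layout (mirrored
    hemisections, left x < 0), inverse-warped through a random invertible
    hemisection distortion, rigidly rotated and translated, and finally
    jittered (cells only — anchors stay exactly on the rigid+distortion
    transform).  Registration of the raw outputs recovers ``template_truth``
    exactly when ``jitter_sd`` is 0.
    """
    spec = spec or TemplateSpec.for_segment(cfg.segment_group)
    ss = np.random.SeedSequence(cfg.seed)
    r_place, r_warp, r_jitter = (np.random.default_rng(s) for s in ss.spawn(3))

    # --- template-frame placement ------------------------------------------
    names = list(cfg.family_layout)
    weights = np.array([cfg.family_layout[n].weight for n in names], dtype=float)
    weights = weights / weights.sum()
    fam_idx = r_place.choice(len(names), size=cfg.n_cells, p=weights)
    mean_y = np.array([cfg.family_layout[n].mean_y for n in names])[fam_idx]
    sd_y = np.array([cfg.family_layout[n].sd_y for n in names])[fam_idx]
    mean_x = np.array([cfg.family_layout[n].mean_abs_x for n in names])[fam_idx]
    sd_x = np.array([cfg.family_layout[n].sd_x for n in names])[fam_idx]
    side = r_place.choice([-1.0, 1.0], size=cfg.n_cells)
    y_t = r_place.normal(mean_y, sd_y)
    x_t = side * np.abs(r_place.normal(mean_x, sd_x))
    # keep cells inside the anchored template span so the warp is interpolative
    y_t = np.clip(y_t, spec.y_ventral * 0.98, spec.y_dorsal * 0.98)

    families = np.array(names, dtype=object)[fam_idx]
    template_truth = make_cell_table(
        x_t,
        y_t,
        section_id=cfg.section_id,
        type_label=families,
        family_label=families,
        genotype=cfg.genotype,
        segment_group=cfg.segment_group,
        frame="template",
    )

    # --- invertible template -> "raw anatomy" distortion --------------------
    factors = _distortion_factors(r_warp, cfg.warp_strength)
    template_anchors = spec.anchor_positions()
    raw_ctrl: dict[str, dict[str, float]] = {}
    for s in ("L", "R"):
        raw_ctrl[s] = {
            "y_ventral": spec.y_ventral * factors[f"y_ventral_{s}"],
            "y_vlat": spec.y_vlat * factors[f"y_vlat_{s}"],
            "y_junction": 0.0,
            "y_lat": spec.y_lat * factors[f"y_lat_{s}"],
            "y_dc": spec.y_dc * factors["y_dc"],  # midline level, shared
            "y_dorsal": spec.y_dorsal * factors[f"y_dorsal_{s}"],
        }

    def y_to_raw(y: np.ndarray, s: str) -> np.ndarray:
        c = raw_ctrl[s]
        src = np.array(
            [spec.y_ventral, spec.y_vlat, 0.0, spec.y_lat, spec.y_dc, spec.y_dorsal]
        )
        dst = np.array(
            [c["y_ventral"], c["y_vlat"], c["y_junction"], c["y_lat"], c["y_dc"], c["y_dorsal"]]
        )
        return np.interp(y, src, dst)

    def x_to_raw(x: np.ndarray, y_raw: np.ndarray, s: str) -> np.ndarray:
        # The forward warp will derive scales s_dh = 1/u and s_vh = 1/v from
        # the raw lateral anchors and blend THEM linearly in y; dividing by
        # exactly that blend makes the forward warp the exact inverse.
        u = factors[f"x_dh_{s}"]
        v = factors[f"x_vh_{s}"]
        c = raw_ctrl[s]
        t = np.clip((y_raw - c["y_vlat"]) / (c["y_lat"] - c["y_vlat"]), 0.0, 1.0)
        fwd_scale = (1.0 / v) + t * ((1.0 / u) - (1.0 / v))
        return x / fwd_scale

    def distort(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        out_x = np.empty_like(x)
        out_y = np.empty_like(y)
        for s, mask in (("L", x < 0), ("R", x >= 0)):
            out_y[mask] = y_to_raw(y[mask], s)
            out_x[mask] = x_to_raw(x[mask], out_y[mask], s)
        return out_x, out_y

    cells_x, cells_y = distort(x_t.copy(), y_t.copy())
    anchor_raw: dict[AnchorRole, tuple[float, float]] = {}
    for role, (ax, ay) in template_anchors.items():
        rx, ry = distort(np.array([ax]), np.array([ay]))
        anchor_raw[role] = (float(rx[0]), float(ry[0]))

    # --- rigid motion + jitter ----------------------------------------------
    theta = np.deg2rad(cfg.rotation_deg)
    c, s_ = np.cos(theta), np.sin(theta)
    tx, ty = cfg.translation

    def rigid(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return c * x - s_ * y + tx, s_ * x + c * y + ty

    cells_x, cells_y = rigid(cells_x, cells_y)
    if cfg.jitter_sd > 0:
        cells_x = cells_x + r_jitter.normal(0.0, cfg.jitter_sd, size=cfg.n_cells)
        cells_y = cells_y + r_jitter.normal(0.0, cfg.jitter_sd, size=cfg.n_cells)
    anchors = {}
    for role, (ax, ay) in anchor_raw.items():
        gx, gy = rigid(np.array([ax]), np.array([ay]))
        anchors[role] = (float(gx[0]), float(gy[0]))

    raw_cells = make_cell_table(
        cells_x,
        cells_y,
        section_id=cfg.section_id,
        type_label=families,
        family_label=families,
        genotype=cfg.genotype,
        segment_group=cfg.segment_group,
        frame="raw",
    )
    landmarks = SectionLandmarks(cfg.section_id, anchors, frame="raw")
    return raw_cells, landmarks, template_truth


# ---------------------------------------------------------------------------
# EdU birthdating counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BirthWave:
    """Gaussian birth wave of one family: center (embryonic day) and width."""

    mu_birth: float
    sigma_birth: float


#: Six temporal cohorts at half-day offsets across the neurogenic window,
#: matching the pulse design of half-day injections from E10.5 to E13.5.
DEFAULT_BIRTH_WAVES: dict[str, BirthWave] = {
    "fam1": BirthWave(10.9, 0.40),
    "fam2": BirthWave(11.4, 0.40),
    "fam3": BirthWave(11.9, 0.40),
    "fam4": BirthWave(12.4, 0.40),
    "fam5": BirthWave(12.9, 0.40),
    "fam6": BirthWave(13.3, 0.40),
}

DEFAULT_TIMEPOINTS = (10.5, 11.0, 11.5, 12.0, 12.5, 13.0, 13.5)


@dataclass(frozen=True)
class BirthSimConfig:
    families: Mapping[str, BirthWave] = field(
        default_factory=lambda: dict(DEFAULT_BIRTH_WAVES)
    )
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS
    n_litters: int = 4
    n_embryos_per_litter: int = 3
    n_cells_per_embryo: int = 100
    #: length (days) of the labeling window a pulse integrates over; the pulse
    #: timestamp marks the END of the window, so a pulse at t tags cells with
    #: birthdate in (t - edu_window, t].
    edu_window: float = 0.5
    #: SD (days) of litter-level conception-time jitter; off by default.
    litter_time_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.timepoints) == 0:
            raise ConfigurationError("timepoints must not be empty")
        tp = np.asarray(self.timepoints, dtype=float)
        if not np.all(np.diff(tp) > 0):
            raise ConfigurationError("timepoints must be strictly increasing")
        if not self.families:
            raise ConfigurationError("families must not be empty")
        for name, wave in self.families.items():
            if wave.sigma_birth <= 0:
                raise ConfigurationError(f"family {name!r} has sigma_birth <= 0")
        if min(self.n_litters, self.n_embryos_per_litter, self.n_cells_per_embryo) <= 0:
            raise ConfigurationError("design counts must be positive")
        if self.edu_window <= 0:
            raise ConfigurationError("edu_window must be positive")


def make_birth_counts(cfg: BirthSimConfig) -> pd.DataFrame:
    """Simulate an EdU co-labeling count table.

    For every litter, embryo, family and pulse timepoint t, ``n_marker``
    marker-positive cells are examined (an independent section per pulse);
    each cell's birthdate is drawn from the family's Gaussian wave and the
    cell is EdU co-labeled iff its birthdate falls in the half-day window
    ending at the pulse, (t - edu_window, t].  Columns:
    litter_id, embryo_id, timepoint, family, n_marker, n_colabel.
    """
    ss = np.random.SeedSequence(cfg.seed)
    litter_streams = ss.spawn(cfg.n_litters)
    rows = []
    for li, litter_ss in enumerate(litter_streams, start=1):
        rng = np.random.default_rng(litter_ss)
        t_offset = (
            rng.normal(0.0, cfg.litter_time_jitter_sd)
            if cfg.litter_time_jitter_sd > 0
            else 0.0
        )
        for ei in range(1, cfg.n_embryos_per_litter + 1):
            for fam, wave in cfg.families.items():
                for t in cfg.timepoints:
                    births = rng.normal(
                        wave.mu_birth, wave.sigma_birth, size=cfg.n_cells_per_embryo
                    )
                    t_eff = t + t_offset
                    labeled = (births > t_eff - cfg.edu_window) & (births <= t_eff)
                    rows.append(
                        {
                            "litter_id": f"L{li}",
                            "embryo_id": f"L{li}E{ei}",
                            "timepoint": float(t),
                            "family": fam,
                            "n_marker": cfg.n_cells_per_embryo,
                            "n_colabel": int(labeled.sum()),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Composition time series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TypeWave:
    """One cell type's Gaussian prominence over developmental time."""

    mu_peak: float
    sigma: float
    weight: float = 1.0


def _quarter_day_grid(start: float = 11.0, stop: float = 16.75) -> tuple[float, ...]:
    return tuple(np.round(np.arange(start, stop + 1e-9, 0.25), 2))


@dataclass(frozen=True)
class CompositionSimConfig:
    types: Mapping[str, TypeWave] = field(
        default_factory=lambda: {
            "fam1": TypeWave(11.0, 0.6),
            "fam2": TypeWave(11.5, 0.6),
            "fam3": TypeWave(12.0, 0.6),
            "fam4": TypeWave(12.5, 0.6),
            "fam5": TypeWave(13.0, 0.6),
            "fam6": TypeWave(13.5, 0.6),
        }
    )
    timepoints: Sequence[float] = field(default_factory=_quarter_day_grid)
    n_cells_per_timepoint: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.types:
            raise ConfigurationError("types must not be empty")
        for name, wave in self.types.items():
            if wave.weight <= 0:
                raise ConfigurationError(f"type {name!r} has non-positive weight")
            if wave.sigma <= 0:
                raise ConfigurationError(f"type {name!r} has sigma <= 0")
        tp = np.asarray(self.timepoints, dtype=float)
        if len(tp) < 2 or not np.all(np.diff(tp) > 0):
            raise ConfigurationError("timepoints must be strictly increasing, length >= 2")
        if self.n_cells_per_timepoint <= 0:
            raise ConfigurationError("n_cells_per_timepoint must be positive")


def make_composition_series(cfg: CompositionSimConfig) -> list[CompositionSeries]:
    """Sampled cell-type proportion curves over the timepoint grid.

    At each timepoint the expected composition is the normalized product of
    each type's weight and its Gaussian density at that time; observed counts
    are a single multinomial draw, so per-timepoint proportions across types
    sum to 1 exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    names = list(cfg.types)
    tp = np.asarray(cfg.timepoints, dtype=float)
    props = np.empty((len(tp), len(names)))
    for i, t in enumerate(tp):
        dens = np.array(
            [
                w.weight * np.exp(-0.5 * ((t - w.mu_peak) / w.sigma) ** 2) / w.sigma
                for w in cfg.types.values()
            ]
        )
        probs = dens / dens.sum()
        counts = rng.multinomial(cfg.n_cells_per_timepoint, probs)
        props[i] = counts / cfg.n_cells_per_timepoint
    return [
        CompositionSeries(label=name, x=tp, v=props[:, j], compositional=True)
        for j, name in enumerate(names)
    ]


# ---------------------------------------------------------------------------
# Depth profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfilePeak:
    """One Gaussian bump of signal in a raw depth profile (bins are 1-based)."""

    center_bin: float
    width: float
    amplitude: float


def _default_profile_peaks() -> dict[tuple[str, str], tuple[ProfilePeak, ...]]:
    # control: a superficial band; mutant: the same marker shifted deeper.
    return {
        ("ctrl", "markerA"): (ProfilePeak(40.0, 12.0, 1.0),),
        ("mut", "markerA"): (ProfilePeak(70.0, 12.0, 1.0),),
        ("ctrl", "markerB"): (ProfilePeak(100.0, 18.0, 0.8),),
        ("mut", "markerB"): (ProfilePeak(100.0, 18.0, 0.8),),
    }


@dataclass(frozen=True)
class ProfileSimConfig:
    n_bins_raw: int = 240
    peaks: Mapping[tuple[str, str], Sequence[ProfilePeak]] = field(
        default_factory=_default_profile_peaks
    )
    noise_sd: float = 0.05
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins_raw <= 0:
            raise ConfigurationError("n_bins_raw must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_replicates <= 0:
            raise ConfigurationError("n_replicates must be positive")
        for (gt, marker), plist in self.peaks.items():
            for p in plist:
                if p.amplitude < 0:
                    raise ConfigurationError(
                        f"({gt}, {marker}): amplitudes must be >= 0"
                    )
                if not 1 <= p.center_bin <= self.n_bins_raw:
                    raise ConfigurationError(
                        f"({gt}, {marker}): center_bin {p.center_bin} outside "
                        f"[1, {self.n_bins_raw}]"
                    )


def make_depth_profiles(cfg: ProfileSimConfig) -> pd.DataFrame:
    """Simulate raw dorsoventral signal profiles (long format).

    Each (genotype, marker, replicate) profile is the sum of its configured
    Gaussian bumps over 1-based bin centers, plus truncated-at-zero Gaussian
    noise.  Columns: genotype, marker, replicate, bin, value; bin 1 is the
    dorsal-most.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    bins = np.arange(1, cfg.n_bins_raw + 1, dtype=float)
    rows = []
    for (gt, marker), plist in cfg.peaks.items():
        signal = np.zeros_like(bins)
        for p in plist:
            signal = signal + p.amplitude * np.exp(
                -0.5 * ((bins - p.center_bin) / p.width) ** 2
            )
        for rep in range(1, cfg.n_replicates + 1):
            values = signal.copy()
            if cfg.noise_sd > 0:
                values = values + rng.normal(0.0, cfg.noise_sd, size=len(bins))
            values = np.clip(values, 0.0, None)
            rows.append(
                pd.DataFrame(
                    {
                        "genotype": gt,
                        "marker": marker,
                        "replicate": rep,
                        "bin": bins.astype(int),
                        "value": values,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
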