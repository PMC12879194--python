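"""Cumulative EdU birthdating curves and sigmoid inflection statistics.

A single EdU pulse at embryonic time t tags the cohort of neurons born around
t; counting, per cell family, the fraction of marker-positive neurons that
carry the EdU label ("co-labeling") across a series of pulse times yields a
birth-rate profile.  This module turns raw co-labeling counts into:

1. litter-level co-labeling fractions (embryos averaged within litter — the
   litter is the biological replicate);
2. cumulative birth curves, normalized so the mean cumulative co-labeling at
   the final pulse time is exactly 100% while within-timepoint variation
   across litters is preserved;
3. sigmoid fits (logistic, 4PL, or asymmetric 5PL) whose half-maximal time is
   the family's half-birthdate (EC50); and
4. pairwise two-sample t-tests, FDR-adjusted, on the distributions of
   per-replicate inflection points and steepness parameters across families.

Model forms (x = embryonic day, y = cumulative percent):

* logistic:  y = Asym / (1 + exp((xmid - x) / scal))
* 4PL:       y = a + (d - a) / (1 + (c / x)^b)          (half-max at x = c)
* 5PL:       y = a + (d - a) / (1 + (c / x)^b)^s
             (half-max at x = c / (2^(1/s) - 1)^(1/b))
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import NoSignalError

logger = logging.getLogger(__name__)

__all__ = [
    "SigmoidFit",
    "CumulativeCurves",
    "colabel_fractions",
    "cumulative_curves",
    "fit_sigmoid",
    "fit_family_curves",
    "replicate_fits",
    "inflection_tests",
]


def colabel_fractions(counts: pd.DataFrame) -> pd.DataFrame:
    """Litter-level co-labeling fractions from an EdU count table.

    Input columns: litter_id, embryo_id, timepoint, family, n_marker,
    n_colabel.  Each embryo contributes n_colabel / n_marker; the mean across
    a litter's embryos is that litter's single data point.  Litter-timepoints
    with zero marker cells in every embryo yield a missing value (never 0)
    and are logged.
    """
    required = {"litter_id", "embryo_id", "timepoint", "family", "n_marker", "n_colabel"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table lacks columns: {sorted(missing)}")
    if (counts["n_colabel"] > counts["n_marker"]).any():
        raise ValueError("n_colabel exceeds n_marker in some rows")
    df = counts.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        df["frac"] = np.where(
            df["n_marker"] > 0, df["n_colabel"] / df["n_marker"], np.nan
        )
    out = (
        df.groupby(["litter_id", "timepoint", "family"], sort=True)["frac"]
        .mean()
        .rename("fraction")
        .reset_index()
    )
    n_missing = int(out["fraction"].isna().sum())
    if n_missing:
        logger.warning(
            "colabel_fractions: %d litter-timepoint(s) had no marker cells; "
            "fractions set to missing",
            n_missing,
        )
    return out


@dataclass(frozen=True)
class CumulativeCurves:
    """Cumulative birth curves for one or more families.

    ``replicates`` holds the litter-level cumulative percentages (litter_id,
    timepoint, family, cumulative_percent); ``summary`` holds, per family and
    timepoint, the litter-mean fraction ``mean_fraction``, the normalized
    percent born at that timepoint ``percent_born`` (summing to 100 across
    timepoints), and the mean cumulative percent ``mean_cumulative`` (100 at
    the final timepoint by construction).
    """

    replicates: pd.DataFrame
    summary: pd.DataFrame


def cumulative_curves(fractions: pd.DataFrame) -> CumulativeCurves:
    """Build normalized cumulative birth curves from litter fractions.

    Per family: m_t = complete-case litter mean of the fraction at timepoint
    t; p_t = 100 * m_t / sum_t m_t (the percent born at t); each litter's
    replicate value r_{l,t} = 100 * f_{l,t} / sum_t m_t; and the cumulative
    C_{l,t} = r_{l,t} + sum_{s<t} p_s, which preserves within-timepoint
    spread while pinning the litter-mean cumulative at the final timepoint to
    exactly 100%.
    """
    required = {"litter_id", "timepoint", "family", "fraction"}
    missing = required - set(fractions.columns)
    if missing:
        raise ValueError(f"fraction table lacks columns: {sorted(missing)}")
    rep_parts, sum_parts = [], []
    for family, grp in fractions.groupby("family", sort=True):
        means = grp.groupby("timepoint", sort=True)["fraction"].mean()
        total = means.sum(skipna=True)
        if not total > 0:
            raise NoSignalError(
                f"family {family!r}: all mean co-labeling fractions are zero"
            )
        pct = 100.0 * means / total
        prior = pct.cumsum().shift(1, fill_value=0.0)
        g = grp.copy()
        g["replicate_percent"] = 100.0 * g["fraction"] / total
        g["cumulative_percent"] = (
            g["replicate_percent"] + g["timepoint"].map(prior).astype(float)
        )
        rep_parts.append(
            g[["litter_id", "timepoint", "family", "cumulative_percent"]]
        )
        sum_parts.append(
            pd.DataFrame(
                {
                    "family": family,
                    "timepoint": means.index,
                    "mean_fraction": means.to_numpy(),
                    "percent_born": pct.to_numpy(),
                    "mean_cumulative": pct.cumsum().to_numpy(),
                }
            )
        )
    return CumulativeCurves(
        replicates=pd.concat(rep_parts, ignore_index=True),
        summary=pd.concat(sum_parts, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# Sigmoid fitting
# ---------------------------------------------------------------------------

_N_PARAMS = {"logistic": 3, "4PL": 4, "5PL": 5}


@dataclass(frozen=True)
class SigmoidFit:
    model_requested: str
    model_used: str
    params: Mapping[str, float] | None
    half_max: float
    rss: float
    r_squared: float
    converged: bool
    message: str = ""

    def predict(self, x) -> np.ndarray:
        if self.params is None:
            raise ValueError("fit did not converge; no parameters to predict with")
        return _MODELS[self.model_used](np.asarray(x, dtype=float), self.params)


def _logistic(x: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    return p["Asym"] / (1.0 + np.exp((p["xmid"] - x) / p["scal"]))


def _fourpl(x: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    return p["a"] + (p["d"] - p["a"]) / (1.0 + (p["c"] / x) ** p["b"])


def _fivepl(x: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    return p["a"] + (p["d"] - p["a"]) / (1.0 + (p["c"] / x) ** p["b"]) ** p["s"]


_MODELS = {"logistic": _logistic, "4PL": _fourpl, "5PL": _fivepl}


def _half_max(model: str, p: Mapping[str, float]) -> float:
    if model == "logistic":
        return p["xmid"]
    if model == "4PL":
        return p["c"]
    return p["c"] / (2.0 ** (1.0 / p["s"]) - 1.0) ** (1.0 / p["b"])


def _setup(model: str, x: np.ndarray, y: np.ndarray):
    """Initial values and bounds, derived from the data per the usual rules:
    bottom/top from the y-range, c from the half-range crossing, slope sign
    from the overall trend."""
    span = x.max() - x.min()
    ymin, ymax = float(y.min()), float(y.max())
    yr = max(ymax - ymin, 1e-9)
    increasing = y[np.argmax(x)] >= y[np.argmin(x)]
    half = (ymin + ymax) / 2.0
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    crossings = np.nonzero(np.diff(np.sign(ys - half)))[0]
    c0 = float(xs[crossings[0]]) if len(crossings) else float(np.median(x))

    if model == "logistic":
        names = ("Asym", "xmid", "scal")
        scal0 = span / 8.0 if increasing else -span / 8.0
        p0 = [ymax, c0, scal0]
        lo = [1e-9, x.min() - 2 * span, 1e-4 * span if increasing else -10 * span]
        hi = [10 * max(abs(ymax), 1.0), x.max() + 2 * span,
              10 * span if increasing else -1e-4 * span]
    elif model == "4PL":
        names = ("a", "d", "c", "b")
        b0 = 5.0 if increasing else -5.0
        p0 = [ymin, ymax, c0, b0]
        lo = [ymin - 2 * yr, ymax - 2 * yr, max(x.min() / 4.0, 1e-6),
              1e-2 if increasing else -200.0]
        hi = [ymin + 2 * yr, ymax + 2 * yr, x.max() * 4.0,
              200.0 if increasing else -1e-2]
    else:  # 5PL
        names = ("a", "d", "c", "b", "s")
        b0 = 5.0 if increasing else -5.0
        p0 = [ymin, ymax, c0, b0, 1.0]
        lo = [ymin - 2 * yr, ymax - 2 * yr, max(x.min() / 4.0, 1e-6),
              1e-2 if increasing else -200.0, 0.05]
        hi = [ymin + 2 * yr, ymax + 2 * yr, x.max() * 4.0,
              200.0 if increasing else -1e-2, 20.0]
    p0 = np.clip(p0, lo, hi)
    return names, np.asarray(p0, float), (np.asarray(lo, float), np.asarray(hi, float))


def _fit_one(model: str, x: np.ndarray, y: np.ndarray) -> SigmoidFit:
    names, p0, bounds = _setup(model, x, y)
    fn = _MODELS[model]

    def resid(theta: np.ndarray) -> np.ndarray:
        return fn(x, dict(zip(names, theta))) - y

    try:
        res = optimize.least_squares(
            resid, p0, bounds=bounds, xtol=1e-10, ftol=1e-10, gtol=1e-10,
            max_nfev=10_000,
        )
    except Exception as exc:  # numerical blow-up inside the model
        return SigmoidFit(model, model, None, np.nan, np.nan, np.nan, False, str(exc))
    params = dict(zip(names, (float(v) for v in res.x)))
    rss = float(np.sum(res.fun**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    ok = bool(res.success) and np.isfinite(res.x).all()
    return SigmoidFit(
        model_requested=model,
        model_used=model,
        params=params if ok else None,
        half_max=_half_max(model, params) if ok else np.nan,
        rss=rss,
        r_squared=r2,
        converged=ok,
        message=res.message,
    )


def fit_sigmoid(
    x: Sequence[float],
    y: Sequence[float],
    model: str = "4PL",
    fallback_r2: float = 0.95,
) -> SigmoidFit:
    """Bounded nonlinear least-squares sigmoid fit.

    ``model`` is "logistic", "4PL" or "5PL".  A 4PL request falls back to the
    asymmetric 5PL when the 4PL fit fails to converge or its R² falls below
    ``fallback_r2`` (curves with a negligible slow-growth phase); the result's
    ``model_used`` records which form produced the parameters.  Total
    non-convergence yields a flagged failure result, not an exception.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(np.unique(x)) < _N_PARAMS[model]:
        raise ValueError(
            f"{model} needs at least {_N_PARAMS[model]} distinct x values"
        )
    if model in ("4PL", "5PL") and (x <= 0).any():
        raise ValueError("4PL/5PL require positive x (concentration-style axis)")

    fit = _fit_one(model, x, y)
    if model == "4PL" and (
        not fit.converged or (np.isfinite(fit.r_squared) and fit.r_squared < fallback_r2)
    ):
        if len(np.unique(x)) >= _N_PARAMS["5PL"]:
            alt = _fit_one("5PL", x, y)
            if alt.converged:
                logger.info(
                    "fit_sigmoid: 4PL fit inadequate (converged=%s, R2=%.4f); "
                    "using 5PL fallback",
                    fit.converged,
                    fit.r_squared,
                )
                return SigmoidFit(
                    model_requested="4PL",
                    model_used="5PL",
                    params=alt.params,
                    half_max=alt.half_max,
                    rss=alt.rss,
                    r_squared=alt.r_squared,
                    converged=True,
                    message=alt.message,
                )
    return fit


def fit_family_curves(
    curves: CumulativeCurves,
    model: str = "4PL",
    on: str = "replicates",
    fallback_r2: float = 0.95,
) -> dict[str, SigmoidFit]:
    """One sigmoid fit per family, on pooled litter replicates or on means."""
    if on not in ("replicates", "means"):
        raise ValueError("on must be 'replicates' or 'means'")
    fits: dict[str, SigmoidFit] = {}
    if on == "replicates":
        for family, grp in curves.replicates.groupby("family", sort=True):
            g = grp.dropna(subset=["cumulative_percent"])
            fits[family] = fit_sigmoid(
                g["timepoint"], g["cumulative_percent"], model, fallback_r2
            )
    else:
        for family, grp in curves.summary.groupby("family", sort=True):
            fits[family] = fit_sigmoid(
                grp["timepoint"], grp["mean_cumulative"], model, fallback_r2
            )
    return fits


def replicate_fits(
    curves: CumulativeCurves, model: str = "logistic"
) -> dict[str, list[SigmoidFit]]:
    """Per-litter sigmoid fits of each family's cumulative series.

    Litters whose fit fails to converge are dropped with a warning; the
    returned lists feed :func:`inflection_tests`.
    """
    out: dict[str, list[SigmoidFit]] = {}
    for (family, litter), grp in curves.replicates.groupby(
        ["family", "litter_id"], sort=True
    ):
        g = grp.dropna(subset=["cumulative_percent"])
        try:
            fit = fit_sigmoid(g["timepoint"], g["cumulative_percent"], model)
        except ValueError as exc:
            logger.warning("replicate_fits: %s/%s skipped (%s)", family, litter, exc)
            continue
        if not fit.converged:
            logger.warning(
                "replicate_fits: %s/%s did not converge; dropped", family, litter
            )
            continue
        out.setdefault(family, []).append(fit)
    return out


def inflection_tests(
    fits_by_family: Mapping[str, Sequence[SigmoidFit]],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Pairwise t-tests on inflection point and steepness across families.

    For every family pair, two-sample t-tests (equal-variance by default,
    Welch via ``equal_var=False``) compare the distributions of per-replicate
    inflection times (``half_max``; the logistic ``xmid``) and, where the
    fits expose it, of the steepness parameter ``scal``.  p-values are
    Benjamini-Hochberg adjusted separately within each statistic's set of
    family pairs.  Pairs with zero variance in both groups and equal means
    yield an undefined t reported as missing.
    """
    families = sorted(fits_by_family)
    if any(len(fits_by_family[f]) < 2 for f in families):
        raise ValueError("need >= 2 converged replicate fits per family")

    def extract(fam: str, stat: str) -> np.ndarray | None:
        vals = []
        for fit in fits_by_family[fam]:
            if stat == "xmid":
                vals.append(fit.half_max)
            else:
                if fit.params is None or "scal" not in fit.params:
                    return None
                vals.append(fit.params["scal"])
        return np.asarray(vals, dtype=float)

    rows = []
    for stat in ("xmid", "scal"):
        groups = {f: extract(f, stat) for f in families}
        if any(v is None for v in groups.values()):
            continue  # steepness unavailable for non-logistic fits
        stat_rows = []
        for i, fa in enumerate(families):
            for fb in families[i + 1 :]:
                va, vb = groups[fa], groups[fb]
                if va.std() == 0 and vb.std() == 0:
                    t_val, p_val = (np.nan, np.nan)  # undefined t
                else:
                    t_val, p_val = stats.ttest_ind(va, vb, equal_var=equal_var)
                df_val = (
                    len(va) + len(vb) - 2
                    if equal_var
                    else np.nan  # Welch df left to the reader of t/p
                )
                stat_rows.append(
                    {
                        "family_a": fa,
                        "family_b": fb,
                        "statistic": stat,
                        "t": float(t_val) if np.isfinite(t_val) else np.nan,
                        "df": df_val,
                        "p": float(p_val) if np.isfinite(p_val) else np.nan,
                    }
                )
        pvals = np.array([r["p"] for r in stat_rows])
        finite = np.isfinite(pvals)
        q = np.full_like(pvals, np.nan)
        if finite.any():
            q[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
        for r, qv in zip(stat_rows, q):
            r["q"] = qv
        rows.extend(stat_rows)
    return pd.DataFrame(rows)
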