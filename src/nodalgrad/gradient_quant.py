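"""Quantitative gradient read-outs from per-nucleus intensity tables.

Turns tables in the per-nucleus source-data schema (one row per
segmented nucleus: GFP, pSmad2Raw, "pSmad2 Normalized", DAPI,
marginDist, GFP_Flag, "Embryo Number") into the assay's quantitative
summaries:

* ``classify_gfp`` - sensor vs host calling against a sliding-window
  median GFP baseline (sensor: > 3x local baseline; host: <= baseline;
  everything in between is left unclassified and excluded downstream).
* ``normalize_psmad2`` - per-embryo normalization of raw pSmad2 staining
  to the far-field baseline (mean over nuclei 150-200 um from the
  margin), so the normalized far field sits at 1.
* ``pool_and_window`` - pool nuclei across embryos and compile the
  sliding-window (20 um) mean gradient on a regular distance grid.
* ``fit_exponential`` - nonlinear least-squares fit of
  ``A * exp(b * d) + c`` with 95% confidence half-widths.
* ``half_distance`` - distance at which the above-baseline window curve
  falls to half its margin-proximal value.
* ``stage_kymograph`` - pixel-binned mean-intensity columns per
  developmental stage, averaged across embryos.
* ``quantify_clone_profile`` - background-subtracted, binned, smoothed
  and source-normalized intensity profile next to a transplanted clone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "GradientProfile",
    "ExpFit",
    "StageKymograph",
    "classify_gfp",
    "normalize_psmad2",
    "pool_and_window",
    "fit_exponential",
    "half_distance",
    "stage_kymograph",
    "quantify_clone_profile",
]


@dataclass
class GradientProfile:
    """Pooled per-nucleus points plus their sliding-window mean curve."""

    distances: np.ndarray          # marginDist per nucleus (um)
    values: np.ndarray             # normalized intensity per nucleus
    embryo: np.ndarray             # embryo id per nucleus
    grid: np.ndarray               # regular distance grid (um)
    curve: np.ndarray              # window mean on the grid (NaN where undefined)
    window: float = 20.0

    @property
    def n(self) -> int:
        return self.distances.size


@dataclass
class ExpFit:
    """Single-exponential fit ``A * exp(b * d) + c`` with 95% CIs."""

    A: float
    b: float
    c: float
    ci_A: float
    ci_b: float
    ci_c: float
    rss: float
    n: int

    def predict(self, d: np.ndarray) -> np.ndarray:
        return self.A * np.exp(self.b * np.asarray(d)) + self.c

    def to_dict(self) -> dict:
        return {"A": self.A, "b": self.b, "c": self.c,
                "ci_A": self.ci_A, "ci_b": self.ci_b, "ci_c": self.ci_c,
                "rss": self.rss, "n": self.n}


@dataclass
class StageKymograph:
    """Mean intensity vs margin-distance bins, one column per stage."""

    stages: list[str]
    bin_edges: np.ndarray          # shared bin edges (um)
    matrix: np.ndarray             # (n_bins, n_stages), NaN where empty
    embryo_counts: list[int]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _sliding_stat(dist, val, grid, window, stat, min_points):
    """Centered sliding-window statistic of val over dist, on grid."""
    half = window / 2.0
    out = np.full(grid.size, np.nan)
    order = np.argsort(dist)
    d, v = np.asarray(dist)[order], np.asarray(val)[order]
    lo = np.searchsorted(d, grid - half, side="left")
    hi = np.searchsorted(d, grid + half, side="right")
    for i, (a, b) in enumerate(zip(lo, hi)):
        if b - a >= min_points:
            out[i] = stat(v[a:b])
    return out


def classify_gfp(
    records: pd.DataFrame,
    baseline_window: float = 40.0,
    positive_factor: float = 3.0,
    min_per_window: int = 10,
) -> pd.DataFrame:
    """Set ``GFP_Flag`` from GFP intensity vs a local sliding-median baseline.

    The baseline GFP level (background antibody staining) at each
    nucleus's margin distance is the sliding-window median of GFP over
    ``baseline_window`` um.  Nuclei brighter than ``positive_factor``
    times the local baseline are flagged 1 (sensor), nuclei at or below
    the baseline 0 (host), everything in between -1 (unclassified,
    excluded from downstream gradients).  Windows holding fewer than
    ``min_per_window`` nuclei borrow the nearest defined window's
    baseline (logged).
    """
    out = records.copy()
    d = out["marginDist"].to_numpy(dtype=float)
    g = out["GFP"].to_numpy(dtype=float)
    grid = np.unique(d)
    base = _sliding_stat(d, g, grid, baseline_window, np.median, min_per_window)
    if np.isnan(base).any():
        defined = np.nonzero(~np.isnan(base))[0]
        if defined.size == 0:
            raise ValueError("no window holds enough nuclei to define a GFP baseline")
        missing = np.nonzero(np.isnan(base))[0]
        logger.info("GFP baseline undefined in %d windows; using nearest defined window",
                    missing.size)
        for i in missing:
            base[i] = base[defined[np.argmin(np.abs(grid[defined] - grid[i]))]]
    local = base[np.searchsorted(grid, d)]
    flag = np.full(d.size, -1, dtype=int)
    flag[g > positive_factor * local] = 1
    flag[g <= local] = 0
    out["GFP_Flag"] = flag
    return out


def normalize_psmad2(
    records: pd.DataFrame,
    baseline_range: tuple[float, float] = (150.0, 200.0),
) -> pd.DataFrame:
    """Fill ``pSmad2 Normalized`` by per-embryo far-field normalization.

    For each embryo, raw pSmad2 intensities are divided by the mean raw
    intensity of that embryo's nuclei with marginDist inside
    ``baseline_range`` (inclusive).  Embryos with no baseline nuclei are
    dropped (logged).
    """
    lo, hi = baseline_range
    out = records.copy()
    kept = []
    for embryo, grp in out.groupby("Embryo Number", sort=False):
        inb = grp["marginDist"].between(lo, hi)
        if not inb.any():
            logger.warning("embryo %s has no nuclei in the %g-%g um baseline band; excluded",
                           embryo, lo, hi)
            continue
        baseline = grp.loc[inb, "pSmad2Raw"].mean()
        g = grp.copy()
        g["pSmad2 Normalized"] = g["pSmad2Raw"] / baseline
        kept.append(g)
    if not kept:
        raise ValueError("no embryo has nuclei inside the normalization baseline range")
    return pd.concat(kept, axis=0).sort_index()


_FLAG_FILTERS = {"sensor": (1,), "host": (0,), "all": (0, 1, -1)}


def pool_and_window(
    records: pd.DataFrame,
    select: str = "all",
    window: float = 20.0,
    grid_step: float = 2.0,
    min_per_window: int = 5,
    value_column: str = "pSmad2 Normalized",
) -> GradientProfile:
    """Pool nuclei across embryos and compile the sliding-window gradient.

    ``select`` filters on GFP_Flag: "sensor" (flag 1), "host" (flag 0) or
    "all".  The window mean is centered, unweighted, evaluated every
    ``grid_step`` um over [0, max distance], and left NaN where fewer
    than ``min_per_window`` nuclei fall inside the window.
    """
    if select not in _FLAG_FILTERS:
        raise ValueError(f"select must be one of {sorted(_FLAG_FILTERS)}")
    sel = records[records["GFP_Flag"].isin(_FLAG_FILTERS[select])]
    sel = sel.dropna(subset=[value_column, "marginDist"])
    if sel.empty:
        raise ValueError(f"no records selected with filter {select!r}")
    d = sel["marginDist"].to_numpy(dtype=float)
    v = sel[value_column].to_numpy(dtype=float)
    grid = np.arange(0.0, d.max() + grid_step / 2, grid_step)
    curve = _sliding_stat(d, v, grid, window, np.mean, min_per_window)
    return GradientProfile(distances=d, values=v,
                           embryo=sel["Embryo Number"].to_numpy(),
                           grid=grid, curve=curve, window=window)


def _initial_guess(d, v):
    """Data-driven initializer: c from the far field, b from a log-linear fit."""
    c0 = float(np.nanmean(v[d >= np.percentile(d, 75)]))
    prox = v[d <= np.percentile(d, 25)]
    A0 = max(float(np.nanmean(prox)) - c0, 1e-3)
    excess = v - c0
    ok = excess > 0.05 * A0
    if ok.sum() >= 3 and np.ptp(d[ok]) > 0:
        b0 = float(np.polyfit(d[ok], np.log(excess[ok]), 1)[0])
        b0 = min(b0, -1e-4)
    else:
        b0 = -1.0 / max(np.ptp(d) / 4, 1.0)
    return A0, b0, c0


def fit_exponential(
    profile: GradientProfile,
    use: str = "points",
    fix_c: float | None = None,
) -> ExpFit:
    """Nonlinear least-squares single-exponential fit with 95% CIs.

    Fits ``A * exp(b * d) + c`` to the pooled per-nucleus points
    (``use="points"``) or to the defined part of the window curve
    (``use="curve"``).  ``fix_c`` pins the offset (e.g. at the normalized
    far-field value 1) instead of fitting it.

    Confidence half-widths are Student-t intervals from the parameter
    covariance.  When the points pool several embryos, residuals are
    correlated within embryos (each embryo carries its own staining
    amplitude), so the covariance is estimated cluster-robustly by
    embryo (sandwich estimator, t with n_embryos - 1 degrees of
    freedom); otherwise the usual iid least-squares covariance is used.
    The fit is deterministic given identical input.
    """
    embryo = None
    if use == "points":
        d, v = profile.distances, profile.values
        if profile.embryo is not None and np.unique(profile.embryo).size > 1:
            embryo = np.asarray(profile.embryo)
    elif use == "curve":
        ok = ~np.isnan(profile.curve)
        d, v = profile.grid[ok], profile.curve[ok]
    else:
        raise ValueError("use must be 'points' or 'curve'")
    if d.size < 10:
        raise ValueError(f"need >= 10 points to fit, got {d.size}")
    if np.ptp(d) < 2 * profile.window:
        raise ValueError("points must span at least two window widths")

    A0, b0, c0 = _initial_guess(d, v)
    try:
        if fix_c is None:
            popt, pcov = optimize.curve_fit(
                lambda x, A, b, c: A * np.exp(b * x) + c, d, v,
                p0=[A0, b0, c0], maxfev=20000)
            A, b, c = popt
            dof = d.size - 3
        else:
            popt, pcov = optimize.curve_fit(
                lambda x, A, b: A * np.exp(b * x) + fix_c, d, v,
                p0=[A0, b0], maxfev=20000)
            A, b = popt
            c = fix_c
            dof = d.size - 2
    except RuntimeError as err:
        raise RuntimeError(
            f"exponential fit failed to converge (init A={A0:.3g}, b={b0:.3g}, "
            f"c={c0:.3g}): {err}") from err

    resid = v - (A * np.exp(b * d) + c)
    rss = float(resid @ resid)
    if embryo is not None:
        expbd = np.exp(b * d)
        J = np.column_stack([expbd, A * d * expbd])
        if fix_c is None:
            J = np.column_stack([J, np.ones_like(d)])
        bread = np.linalg.inv(J.T @ J)
        meat = np.zeros((J.shape[1], J.shape[1]))
        groups = np.unique(embryo)
        for g in groups:
            score = J[embryo == g].T @ resid[embryo == g]
            meat += np.outer(score, score)
        ngroups = groups.size
        pcov = bread @ meat @ bread * ngroups / (ngroups - 1)
        dof = ngroups - 1
    tval = stats.t.ppf(0.975, max(dof, 1))
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    ci = tval * se
    if fix_c is None:
        ci_A, ci_b, ci_c = ci
    else:
        ci_A, ci_b = ci
        ci_c = 0.0
    return ExpFit(A=float(A), b=float(b), c=float(c),
                  ci_A=float(ci_A), ci_b=float(ci_b), ci_c=float(ci_c),
                  rss=rss, n=int(d.size))


def half_distance(profile: GradientProfile, baseline: float = 1.0) -> float:
    """Distance at which the above-baseline window curve halves.

    Measures the smallest d with ``curve(d) - baseline = 0.5 *
    (curve(d0) - baseline)`` where d0 is the first grid point with a
    defined window mean, interpolating linearly between grid points.
    Returns NaN (logged) when the curve never falls to the half level
    within its defined range.
    """
    ok = np.nonzero(~np.isnan(profile.curve))[0]
    if ok.size == 0:
        raise ValueError("window curve is undefined everywhere")
    excess = profile.curve - baseline
    d0 = ok[0]
    target = 0.5 * excess[d0]
    if target <= 0:
        logger.warning("margin-proximal curve value is at or below baseline; half-distance undefined")
        return float("nan")
    prev = d0
    for i in ok[1:]:
        if excess[i] <= target:
            # linear interpolation between the last defined points straddling the level
            g0, g1 = profile.grid[prev], profile.grid[i]
            e0, e1 = excess[prev], excess[i]
            return float(g0 + (e0 - target) / (e0 - e1) * (g1 - g0))
        prev = i
    logger.warning("window curve never decays to half its proximal value; half-distance undefined")
    return float("nan")


def stage_kymograph(
    stage_data: dict[str, list[tuple[np.ndarray, np.ndarray]]],
    bin_width: float = 10.0,
    max_distance: float | None = None,
) -> StageKymograph:
    """Pixel-binned signaling intensity per stage, averaged over embryos.

    ``stage_data`` maps stage name -> list of per-embryo
    ``(intensity_image, margin_distance_map)`` pairs (both 2D, same
    shape, distances in um; dense maps from
    ``image_analysis.compute_margin_distance``).  Pixels are binned by
    margin distance with shared ``bin_width`` edges and their mean
    intensity averaged across embryos (each embryo weighted equally).
    """
    if not stage_data:
        raise ValueError("no stages given")
    for stage, embryos in stage_data.items():
        if not embryos:
            raise ValueError(f"stage {stage!r} has zero embryos")
    if max_distance is None:
        max_distance = max(dm.max() for embryos in stage_data.values() for _, dm in embryos)
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    nb = edges.size - 1

    stages = list(stage_data)
    mat = np.full((nb, len(stages)), np.nan)
    counts = []
    for j, stage in enumerate(stages):
        per_embryo = []
        for img, dmap in stage_data[stage]:
            if img.shape != dmap.shape:
                raise ValueError("image and distance map shapes differ")
            idx = np.clip(np.digitize(dmap.ravel(), edges) - 1, 0, nb - 1)
            sums = np.bincount(idx, weights=img.ravel().astype(float), minlength=nb)
            npix = np.bincount(idx, minlength=nb)
            with np.errstate(invalid="ignore"):
                per_embryo.append(np.where(npix > 0, sums / np.maximum(npix, 1), np.nan))
        mat[:, j] = np.nanmean(np.column_stack(per_embryo), axis=1)
        counts.append(len(per_embryo))
    return StageKymograph(stages=stages, bin_edges=edges, matrix=mat, embryo_counts=counts)


def quantify_clone_profile(
    image: np.ndarray,
    clone_edge_x: float,
    pixel_size: float = 1.0,
    roi_length: float = 150.0,
    roi_width: float = 40.0,
    roi_center_y: float | None = None,
    background: float = 0.0,
    bin_width: float = 1.0,
    smooth_window: float = 5.0,
    sample_every: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized ligand-intensity profile next to a transplanted source clone.

    From a maximum-intensity projection, a region of interest
    ``roi_length x roi_width`` um starting at the clone boundary
    (``clone_edge_x``, pixel units) is extracted.  The mean background of
    ungrafted control embryos is subtracted, intensities are averaged in
    ``bin_width`` um bins of distance from the clone edge, smoothed with
    a ``smooth_window`` um sliding mean, sampled every ``sample_every``
    um, and normalized to the first sample adjacent to the source.

    Returns ``(sample_distances_um, normalized_profile)``.
    """
    ny, nx = image.shape
    x0 = int(round(clone_edge_x))
    npx = int(round(roi_length / pixel_size))
    if x0 < 0 or x0 + npx > nx:
        raise ValueError("ROI does not fit in the image")
    cy = ny / 2.0 if roi_center_y is None else roi_center_y
    hw = int(round(roi_width / pixel_size / 2))
    y0, y1 = int(round(cy)) - hw, int(round(cy)) + hw
    if y0 < 0 or y1 > ny:
        raise ValueError("ROI does not fit in the image")
    roi = image[y0:y1, x0:x0 + npx].astype(float) - background

    dist = (np.arange(npx) + 0.5) * pixel_size
    prof = roi.mean(axis=0)
    # 1 um binning of the column means
    edges = np.arange(0.0, roi_length + bin_width, bin_width)
    idx = np.clip(np.digitize(dist, edges) - 1, 0, edges.size - 2)
    sums = np.bincount(idx, weights=prof, minlength=edges.size - 1)
    npts = np.bincount(idx, minlength=edges.size - 1)
    binned = sums / np.maximum(npts, 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    half = int(round(smooth_window / bin_width / 2))
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    smoothed = np.convolve(np.pad(binned, half, mode="edge"), kernel, mode="valid")

    step = max(int(round(sample_every / bin_width)), 1)
    samples = smoothed[::step]
    sample_d = centers[::step]
    if samples[0] <= 0:
        raise ValueError("first sample adjacent to the source is <= 0 after "
                         "background subtraction; normalization undefined")
    return sample_d, samples / samples[0]
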