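"""Synthetic fixtures with ground truth for the quantification pipeline.

Two generators cover the two kinds of raw input the pipeline consumes:

* ``make_nucleus_table`` draws per-nucleus tables with the statistical
  structure of the sensor-cell assay: nuclei scattered uniformly in
  margin distance, an exponential signaling gradient ``A_e exp(b d) + c``
  above a unit far-field baseline with per-embryo amplitude variation and
  additive measurement noise, bimodal (log-normal) GFP intensity for
  sensor vs host nuclei, and per-embryo staining-brightness factors that
  convert normalized values into raw intensities.

* ``make_phantom_stack`` renders multi-channel 3D stacks of ellipsoidal
  nuclei behind a curved margin, with out-of-focus haze, background and
  Gaussian noise, so the segmentation stage can be benchmarked against
  exact ground truth.

Both are fully deterministic under a fixed seed, and both return a
ground-truth sidecar sufficient to score every downstream stage without
re-deriving labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_analysis import ImageStack, MarginTrace, RECORD_COLUMNS
from .simulator import FieldSeries

__all__ = ["TableSpec", "StackSpec", "make_nucleus_table", "make_phantom_stack",
           "render_stage_images", "decay_for_half_distance"]


def decay_for_half_distance(
    target_um: float,
    A: float = 3.0,
    c: float = 1.0,
    length: float = 250.0,
    window: float = 20.0,
    grid_step: float = 2.0,
) -> float:
    """Gradient decay b whose noise-free windowed half-distance equals a target.

    The half-distance read-out is defined operationally on the
    sliding-window curve, whose one-sided edge window shifts it a few um
    from the ideal ``ln(2)/|b|``.  To generate a table that *embodies* a
    stated half-distance, this inverts the estimator on the exact
    windowed exponential (uniform nucleus density): the window mean of
    ``A exp(b d) + c`` over ``[d - w/2, d + w/2]`` clipped to the domain
    has the closed form ``A (e^{b hi} - e^{b lo}) / (b (hi - lo)) + c``.
    Solved by bracketing bisection; deterministic.
    """
    from scipy.optimize import brentq

    from .gradient_quant import GradientProfile, half_distance

    def op_half(b: float) -> float:
        grid = np.arange(0.0, length + grid_step / 2, grid_step)
        lo = np.clip(grid - window / 2, 0, length)
        hi = np.clip(grid + window / 2, 0, length)
        curve = A * (np.exp(b * hi) - np.exp(b * lo)) / (b * (hi - lo)) + c
        prof = GradientProfile(distances=grid, values=curve,
                               embryo=np.ones_like(grid), grid=grid, curve=curve,
                               window=window)
        return half_distance(prof)

    return float(brentq(lambda b: op_half(b) - target_um, -0.06, -0.004, xtol=1e-7))


@dataclass(frozen=True)
class TableSpec:
    """Generating model of a sensor-assay per-nucleus table.

    Defaults approximate the assay's replicate structure: 8 embryos of
    ~400 nuclei each over a 250 um margin-distance range, ~10% sensor
    cells, a wild-type-like gradient (A=3, b=-0.02/um) above a unit
    baseline with 20% per-embryo amplitude spread and noise sigma=0.3 in
    normalized units, and sensor GFP ~8-fold above host background.
    """

    n_embryos: int = 8
    nuclei_per_embryo: int = 400
    length: float = 250.0
    A: float = 3.0
    b: float = -0.02
    c: float = 1.0
    amplitude_sigma: float = 0.2     # log-normal sigma of per-embryo amplitude factor
    noise_sigma: float = 0.3         # additive noise SD, normalized units
    sensor_fraction: float = 0.1
    gfp_host_median: float = 10.0
    gfp_host_sigma: float = 0.3      # log-normal shape
    gfp_sensor_median: float = 80.0
    gfp_sensor_sigma: float = 0.4
    brightness_median: float = 200.0  # per-embryo raw-intensity scale
    brightness_sigma: float = 0.3
    dapi_median: float = 150.0
    dapi_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.A < 0 or self.c <= 0 or self.noise_sigma < 0:
            raise ValueError("require A >= 0, c > 0, noise_sigma >= 0")
        if not 0.0 <= self.sensor_fraction <= 1.0:
            raise ValueError("sensor_fraction must be in [0, 1]")


def make_nucleus_table(spec: TableSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a per-nucleus table plus a ground-truth sidecar.

    The table carries the source-data schema columns with
    ``pSmad2 Normalized`` holding the generated noisy gradient value
    (truncated at 0) and ``GFP_Flag`` set to -1 (unclassified) so the
    classifier can be exercised.  The sidecar holds the true label, the
    noise-free gradient value and the per-embryo parameters.
    """
    rng = np.random.default_rng(spec.seed)
    rows, truth_rows = [], []
    for e in range(1, spec.n_embryos + 1):
        n = spec.nuclei_per_embryo
        amp_factor = rng.lognormal(0.0, spec.amplitude_sigma) if spec.amplitude_sigma > 0 else 1.0
        brightness = rng.lognormal(np.log(spec.brightness_median), spec.brightness_sigma)
        d = rng.uniform(0.0, spec.length, n)
        is_sensor = rng.random(n) < spec.sensor_fraction
        clean = spec.A * amp_factor * np.exp(spec.b * d) + spec.c
        noisy = np.clip(clean + rng.normal(0.0, spec.noise_sigma, n), 0.0, None)
        gfp = np.where(
            is_sensor,
            rng.lognormal(np.log(spec.gfp_sensor_median), spec.gfp_sensor_sigma, n),
            rng.lognormal(np.log(spec.gfp_host_median), spec.gfp_host_sigma, n),
        )
        dapi = rng.lognormal(np.log(spec.dapi_median), spec.dapi_sigma, n)
        rows.append(pd.DataFrame({
            "GFP": gfp,
            "pSmad2Raw": noisy * brightness,
            "pSmad2 Normalized": noisy,
            "DAPI": dapi,
            "marginDist": d,
            "GFP_Flag": -1,
            "Embryo Number": e,
        }))
        truth_rows.append(pd.DataFrame({
            "Embryo Number": e,
            "true_sensor": is_sensor.astype(int),
            "true_value": clean,
            "amp_factor": amp_factor,
            "brightness": brightness,
            "marginDist": d,
        }))
    table = pd.concat(rows, ignore_index=True)[RECORD_COLUMNS]
    truth = pd.concat(truth_rows, ignore_index=True)
    truth.attrs["params"] = {"A": spec.A, "b": spec.b, "c": spec.c}
    return table, truth


@dataclass(frozen=True)
class StackSpec:
    """Generating model of a multi-channel 3D phantom stack.

    Nuclei are ellipsoids (in-plane radius drawn per nucleus, axial
    radius in slices) placed without overlap behind a gently curved
    margin.  DAPI is constant per nucleus, pSmad2 follows the TableSpec
    gradient at the nucleus's margin distance, GFP follows the sensor
    label.  Haze is added by mixing in blurred neighbouring-slice
    content, so the out-of-plane subtraction stage has signal to remove.
    """

    shape: tuple[int, int, int] = (14, 512, 512)   # (z, y, x)
    pixel_size_xy: float = 0.5
    z_step: float = 2.0
    n_nuclei: int = 60
    radius_mean: float = 9.0
    radius_sd: float = 1.2
    z_radius: float = 1.8           # slices
    margin_offset: float = 30.0     # px, margin row at x = 0
    margin_curvature: float = 20.0  # px of bowing across the image width
    dapi_amplitude: float = 800.0
    background: float = 40.0
    snr: float = 8.0                # (dapi_amplitude) / noise SD
    haze_amplitude: float = 0.4     # fraction of neighbour content mixed in
    haze_sigma: float = 8.0         # px
    gradient: TableSpec = field(default_factory=TableSpec)
    sensor_fraction: float = 0.1
    psmad2_scale: float = 120.0     # raw counts per normalized unit
    gfp_host_level: float = 15.0
    gfp_sensor_level: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0 or self.snr <= 0:
            raise ValueError("need n_nuclei >= 0 and snr > 0")


def _margin_polyline(spec: StackSpec) -> np.ndarray:
    """Curved margin trace: a bowed polyline across the image, (y, x)."""
    nx = spec.shape[2]
    xs = np.linspace(0, nx - 1, 24)
    ys = spec.margin_offset + spec.margin_curvature * np.sin(np.pi * xs / (nx - 1))
    return np.column_stack([ys, xs])


def make_phantom_stack(
    spec: StackSpec,
) -> tuple[ImageStack, pd.DataFrame, MarginTrace]:
    """Render a phantom stack with exact per-nucleus ground truth.

    Returns ``(stack, truth, trace)`` where ``truth`` has one row per
    placed nucleus: centroid (z, y, x in px), in-plane/axial radii,
    margin distance (um), sensor label and the true mean DAPI / GFP /
    pSmad2 intensities inside the rendered ellipsoid (above background,
    before haze and noise).
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    trace = MarginTrace(_margin_polyline(spec))
    contour = trace.rasterize((ny, nx))
    dmap = ndimage.distance_transform_edt(~contour) * spec.pixel_size_xy
    margin_y = trace.vertices[:, 0]

    # Poisson-disc-style rejection sampling in 3D, anisotropic z
    centers, radii = [], []
    attempts = 0
    z_lo, z_hi = spec.z_radius + 1.2, nz - spec.z_radius - 2.2
    if z_hi < z_lo:  # shallow stacks: centre nuclei axially
        z_lo = z_hi = nz / 2.0
    while len(centers) < spec.n_nuclei:
        attempts += 1
        if attempts > 4000 * max(spec.n_nuclei, 1):
            raise RuntimeError(f"could not place {spec.n_nuclei} nuclei without overlap")
        r = max(rng.normal(spec.radius_mean, spec.radius_sd), 2.0)
        cz = rng.uniform(z_lo, z_hi)
        cy = rng.uniform(margin_y.max() + r + 2, ny - r - 1)
        cx = rng.uniform(r + 1, nx - r - 1)
        ok = True
        for (pz, py, px), pr in zip(centers, radii):
            dz = (cz - pz) * (spec.radius_mean / spec.z_radius)
            if (cy - py) ** 2 + (cx - px) ** 2 + dz ** 2 < (r + pr + 1.5) ** 2:
                ok = False
                break
        if ok:
            centers.append((cz, cy, cx))
            radii.append(r)

    is_sensor = rng.random(len(centers)) < spec.sensor_fraction
    g = spec.gradient

    dapi = np.zeros(spec.shape)
    gfp = np.zeros(spec.shape)
    psmad2 = np.zeros(spec.shape)

    truth_rows = []
    for (cz, cy, cx), r, sensor in zip(centers, radii, is_sensor):
        d_um = float(dmap[int(round(cy)), int(round(cx))])
        # render only inside the nucleus's bounding box
        ext = r * 1.6
        zlo, zhi = max(int(cz - 3 * spec.z_radius), 0), min(int(cz + 3 * spec.z_radius) + 2, nz)
        ylo, yhi = max(int(cy - ext), 0), min(int(cy + ext) + 2, ny)
        xlo, xhi = max(int(cx - ext), 0), min(int(cx + ext) + 2, nx)
        zz = np.arange(zlo, zhi)[:, None, None]
        yy = np.arange(ylo, yhi)[None, :, None]
        xx = np.arange(xlo, xhi)[None, None, :]
        # soft-edged ellipsoid: Gaussian falloff outside the core
        rho2 = (((yy - cy) ** 2 + (xx - cx) ** 2) / r**2 + ((zz - cz) / spec.z_radius) ** 2)
        body = np.exp(-np.clip(rho2 - 0.6, 0.0, None) / 0.25)
        body[rho2 > 2.2] = 0.0
        p_level = spec.psmad2_scale * (g.A * np.exp(g.b * d_um) + g.c)
        g_level = spec.gfp_sensor_level if sensor else spec.gfp_host_level
        box = (slice(zlo, zhi), slice(ylo, yhi), slice(xlo, xhi))
        dapi[box] += spec.dapi_amplitude * body
        gfp[box] += g_level * body
        psmad2[box] += p_level * body
        core = rho2 <= 1.0
        truth_rows.append({
            "centroid_z": cz, "centroid_y": cy, "centroid_x": cx,
            "radius_px": r, "z_radius": spec.z_radius,
            "marginDist": d_um, "true_sensor": int(sensor),
            "true_DAPI": float(dapi[box][core].mean()) if core.any() else np.nan,
            "true_GFP": g_level, "true_pSmad2": p_level,
        })

    # out-of-focus haze: blurred content of the neighbouring slices
    def add_haze(channel: np.ndarray) -> np.ndarray:
        haze = np.zeros_like(channel)
        for i in range(nz):
            nb = [j for j in (i - 1, i + 1) if 0 <= j < nz]
            mixed = np.mean([channel[j] for j in nb], axis=0)
            haze[i] = ndimage.gaussian_filter(mixed, spec.haze_sigma)
        return channel + spec.haze_amplitude * haze

    noise_sd = spec.dapi_amplitude / spec.snr
    out = []
    for ch in (dapi, gfp, psmad2):
        img = add_haze(ch) + spec.background + rng.normal(0.0, noise_sd, spec.shape)
        out.append(np.clip(img, 0.0, 65535.0).astype(np.float32))
    stack = ImageStack(dapi=out[0], gfp=out[1], psmad2=out[2],
                       pixel_size_xy=spec.pixel_size_xy, z_step=spec.z_step)
    truth = pd.DataFrame(truth_rows)
    return stack, truth, trace


def render_stage_images(
    series: FieldSeries,
    spec: StackSpec,
    stage_times: dict[str, float] | None = None,
    species: str = "C",
    intensity_scale: float = 1000.0,
    noise_sigma: float = 2.0,
    seed: int = 0,
) -> dict[str, list[tuple[np.ndarray, np.ndarray]]]:
    """Render per-stage projection images from a 1D simulation.

    Each stage time is mapped to the nearest simulated snapshot; the
    image intensity at a pixel with margin distance d is the simulated
    species profile at d (linear interpolation) scaled by
    ``intensity_scale``, plus Gaussian noise.  Stage times default to
    {T/3, 2T/3, T} for dome, 50% epiboly and shield.  The return value
    feeds ``gradient_quant.stage_kymograph`` directly: stage ->
    [(image, margin-distance map)].
    """
    rng = np.random.default_rng(seed)
    T = series.times[-1]
    if stage_times is None:
        stage_times = {"dome": T / 3.0, "50pct": 2.0 * T / 3.0, "shield": T}
    nz, ny, nx = spec.shape
    trace = MarginTrace(_margin_polyline(spec))
    contour = trace.rasterize((ny, nx))
    dmap = ndimage.distance_transform_edt(~contour) * spec.pixel_size_xy

    out: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for stage, t in stage_times.items():
        if t < series.times[0] - 1e-9 or t > series.times[-1] + 1e-9:
            raise ValueError(f"stage time {t} outside the simulated series")
        i = int(np.argmin(np.abs(series.times - t)))
        prof = series[i].species(species)
        img = intensity_scale * np.interp(dmap, series.x, prof, left=prof[0], right=prof[-1])
        img = img + rng.normal(0.0, noise_sigma, img.shape)
        out[stage] = [(np.clip(img, 0.0, None), dmap)]
    return out
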