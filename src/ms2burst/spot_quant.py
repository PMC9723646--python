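"""Per-nucleus transcription-dot quantification by 2D Gaussian fitting.

For each tracked nucleus and frame, the transcription site is the
brightest voxel within the nucleus across all z-planes. An 11x11 window
on that single z-plane is fit with an elliptical Gaussian on a constant
local background,

    I(x, y) = alpha + I0 * exp(-((x - x0)^2 / (2 sx^2)
                                + (y - y0)^2 / (2 sy^2))),

by ordinary (unweighted) nonlinear least squares, and the spot intensity
is reported as the background-subtracted integral 2*pi*sx*sy*I0. Each
trajectory is then baseline-zeroed by subtracting its minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ms2burst.movie import MovieStack
from ms2burst.segmentation import LabeledFrame
from ms2burst.tracking import TrackTable

SIGMA_MIN = 0.3
SIGMA_MAX = 6.0
WINDOW = 11
MIN_WINDOW = 7  # smallest edge-truncated window still fit


@dataclass
class SpotFit:
    """Result of one single-plane Gaussian fit.

    ``integral`` is the background-subtracted spot intensity
    ``2*pi*sigma_x*sigma_y*I0`` (intensity * px^2); it is 0 whenever
    ``fit_ok`` is False. Peak coordinates are in the coordinate system
    of the full frame, subpixel.
    """

    z_index: int = -1
    x0: float = float("nan")
    y0: float = float("nan")
    amplitude: float = float("nan")
    background: float = float("nan")
    sigma_x: float = float("nan")
    sigma_y: float = float("nan")
    integral: float = 0.0
    fit_ok: bool = False


@dataclass
class TraceSet:
    """Per-track intensity time series.

    For each track: ``raw`` holds the fitted integral per frame (0 where
    the fit failed, NaN where the track is absent), ``baseline_sub`` the
    same trace after subtracting its minimum over covered frames (so the
    minimum is exactly 0). ``start_frame`` anchors index 0 of each
    array on the movie's frame axis.
    """

    start_frame: dict[int, int] = field(default_factory=dict)
    raw: dict[int, np.ndarray] = field(default_factory=dict)
    baseline_sub: dict[int, np.ndarray] = field(default_factory=dict)
    fit_ok: dict[int, np.ndarray] = field(default_factory=dict)
    frame_interval: float = 16.8

    @property
    def track_ids(self) -> list[int]:
        return sorted(self.raw)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for tid in self.track_ids:
            s = self.start_frame[tid]
            for k, (r, b, ok) in enumerate(
                zip(self.raw[tid], self.baseline_sub[tid], self.fit_ok[tid])
            ):
                rows.append((tid, s + k, r, b, bool(ok)))
        return pd.DataFrame(
            rows,
            columns=["track_id", "frame", "raw_integral", "baseline_subtracted", "fit_ok"],
        )

    @classmethod
    def from_table(cls, table: pd.DataFrame, frame_interval: float = 16.8) -> "TraceSet":
        required = {"track_id", "frame", "raw_integral", "baseline_subtracted", "fit_ok"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"trace table missing columns: {sorted(missing)}")
        ts = cls(frame_interval=frame_interval)
        for tid, grp in table.groupby("track_id"):
            grp = grp.sort_values("frame")
            ts.start_frame[int(tid)] = int(grp["frame"].iloc[0])
            ts.raw[int(tid)] = grp["raw_integral"].to_numpy(float)
            ts.baseline_sub[int(tid)] = grp["baseline_subtracted"].to_numpy(float)
            ts.fit_ok[int(tid)] = grp["fit_ok"].to_numpy(bool)
        return ts


def locate_brightest_voxel(
    ms2_frame: np.ndarray, region: np.ndarray
) -> tuple[int, int, int]:
    """Argmax of intensity over ``region`` pixels across all z-planes.

    ``region`` is a boolean (row, col) mask. Ties break toward the
    lowest ``(z, row, col)``.
    """
    ms2_frame = np.asarray(ms2_frame)
    region = np.asarray(region, dtype=bool)
    if ms2_frame.ndim != 3:
        raise ValueError("ms2_frame must be 3-D (z, row, col)")
    if region.shape != ms2_frame.shape[1:]:
        raise ValueError("region mask shape must match frame (row, col)")
    if not region.any():
        raise ValueError("empty region")
    masked = np.where(region[None, :, :], ms2_frame, -np.inf)
    flat = int(np.argmax(masked))  # first max in C order = lowest (z, row, col)
    return np.unravel_index(flat, masked.shape)


def _gauss2d(coords, alpha, i0, x0, y0, sx, sy):
    x, y = coords
    return alpha + i0 * np.exp(
        -((x - x0) ** 2 / (2 * sx**2) + (y - y0) ** 2 / (2 * sy**2))
    )


def _gauss2d_jac(coords, alpha, i0, x0, y0, sx, sy):
    x, y = coords
    dx = x - x0
    dy = y - y0
    e = np.exp(-(dx**2 / (2 * sx**2) + dy**2 / (2 * sy**2)))
    return np.stack(
        [
            np.ones_like(e),
            e,
            i0 * e * dx / sx**2,
            i0 * e * dy / sy**2,
            i0 * e * dx**2 / sx**3,
            i0 * e * dy**2 / sy**3,
        ],
        axis=1,
    )


def fit_gaussian2d(window: np.ndarray, init: SpotFit | None = None) -> SpotFit:
    """Fit the Gaussian-plus-background model to a fit window.

    The window is nominally 11x11 (edge-truncated windows down to 7
    pixels a side are accepted). Coordinates in the returned fit are
    window-local: x = column, y = row. ``fit_ok`` requires convergence,
    a meaningfully positive amplitude, spreads strictly inside
    [0.3, 6] px (a pinned bound signals a degenerate fit), and a peak
    inside the window; otherwise the integral is 0.
    """
    win = np.asarray(window, dtype=float)
    if win.ndim != 2:
        raise ValueError("window must be 2-D")
    if not np.all(np.isfinite(win)):
        raise ValueError("window contains non-finite pixels")
    if min(win.shape) < MIN_WINDOW:
        return SpotFit(fit_ok=False)

    ny, nx = win.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    med = float(np.median(win))
    # no discernible peak above the noise floor -> the Gaussian model is
    # degenerate (I0 -> 0); report a failed fit without iterating
    robust_sd = 1.4826 * float(np.median(np.abs(win - med)))
    if win.max() - med <= max(4.0 * robust_sd, 1e-12):
        return SpotFit(background=med, fit_ok=False)
    if init is None:
        p0 = [med, max(win.max() - med, 1e-3), (nx - 1) / 2, (ny - 1) / 2, 1.5, 1.5]
    else:
        p0 = [init.background, init.amplitude, init.x0, init.y0, init.sigma_x, init.sigma_y]
    lower = [-np.inf, 0.0, 0.0, 0.0, SIGMA_MIN, SIGMA_MIN]
    upper = [np.inf, np.inf, nx - 1.0, ny - 1.0, SIGMA_MAX, SIGMA_MAX]
    p0 = np.clip(p0, lower, upper)

    try:
        popt, _ = curve_fit(
            _gauss2d,
            (xx.ravel(), yy.ravel()),
            win.ravel(),
            p0=p0,
            bounds=(lower, upper),
            jac=_gauss2d_jac,
            x_scale=[1.0, max(abs(p0[1]), 1.0), 1.0, 1.0, 0.5, 0.5],
            ftol=1e-8,
            xtol=1e-8,
            maxfev=200,
        )
    except (RuntimeError, ValueError):
        return SpotFit(fit_ok=False)

    alpha, i0, x0, y0, sx, sy = (float(v) for v in popt)
    eps = 1e-4
    ok = (
        i0 > 1e-3
        and SIGMA_MIN + eps < sx < SIGMA_MAX - eps
        and SIGMA_MIN + eps < sy < SIGMA_MAX - eps
        and 0.0 <= x0 <= nx - 1
        and 0.0 <= y0 <= ny - 1
    )
    integral = 2 * np.pi * sx * sy * i0 if ok else 0.0
    return SpotFit(
        x0=x0,
        y0=y0,
        amplitude=i0,
        background=alpha,
        sigma_x=sx,
        sigma_y=sy,
        integral=integral,
        fit_ok=ok,
    )


def fit_spot_in_frame(
    ms2_frame: np.ndarray, region: np.ndarray, window: int = WINDOW
) -> SpotFit:
    """Locate the brightest voxel in a region and fit its z-plane window."""
    z, row, col = locate_brightest_voxel(ms2_frame, region)
    half = window // 2
    nr, nc = ms2_frame.shape[1:]
    r0, r1 = max(0, row - half), min(nr, row + half + 1)
    c0, c1 = max(0, col - half), min(nc, col + half + 1)
    fit = fit_gaussian2d(ms2_frame[z, r0:r1, c0:c1])
    if fit.fit_ok:
        fit.z_index = int(z)
        fit.x0 += c0  # window-local -> frame coordinates
        fit.y0 += r0
    return fit


def extract_traces(
    movie: MovieStack,
    frames: list[LabeledFrame],
    tracks: TrackTable,
    use_territories: bool = False,
) -> tuple[TraceSet, pd.DataFrame]:
    """Measure every track in every covered frame and baseline-zero.

    Returns the trace set plus the full table of spot fits. The search
    region per frame is the nucleus mask by default (``use_territories``
    switches to the Voronoi cell). Frames where a track is absent are
    marked missing (NaN), not zero, and excluded from the baseline;
    failed fits contribute integral 0.
    """
    by_frame = {lf.frame_index: lf for lf in frames}
    ts = TraceSet(frame_interval=movie.frame_interval)
    fit_rows = []
    for tid, grp in tracks.table.groupby("track_id"):
        tid = int(tid)
        f_lo, f_hi = int(grp["frame"].min()), int(grp["frame"].max())
        n = f_hi - f_lo + 1
        raw = np.full(n, np.nan)
        okv = np.zeros(n, dtype=bool)
        label_of = dict(zip(grp["frame"].astype(int), grp["label"].astype(int)))
        for f in range(f_lo, f_hi + 1):
            lab = label_of.get(f)
            if lab is None or f not in by_frame:
                continue
            lf = by_frame[f]
            src = lf.territories if use_territories else lf.labels
            region = src == lab
            if not region.any():
                continue
            fit = fit_spot_in_frame(movie.ms2_channel[f], region)
            raw[f - f_lo] = fit.integral
            okv[f - f_lo] = fit.fit_ok
            fit_rows.append(
                (
                    tid,
                    f,
                    fit.z_index,
                    fit.x0,
                    fit.y0,
                    fit.amplitude,
                    fit.background,
                    fit.sigma_x,
                    fit.sigma_y,
                    fit.integral,
                    fit.fit_ok,
                )
            )
        valid = ~np.isnan(raw)
        baseline = np.nanmin(raw) if valid.any() else 0.0
        ts.start_frame[tid] = f_lo
        ts.raw[tid] = raw
        ts.baseline_sub[tid] = np.where(valid, raw - baseline, np.nan)
        ts.fit_ok[tid] = okv
    spotfits = pd.DataFrame(
        fit_rows,
        columns=[
            "track_id",
            "frame",
            "z_index",
            "x0",
            "y0",
            "amplitude",
            "background",
            "sigma_x",
            "sigma_y",
            "integral",
            "fit_ok",
        ],
    )
    return ts, spotfits
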