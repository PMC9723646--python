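"""Synthetic two-channel movies with telegraph-model bursting and ground truth.

Promoter activity follows the two-state telegraph model: a promoter
switches ON at rate ``k_on`` and OFF at rate ``k_off`` (continuous-time
Markov chain, simulated exactly with the Gillespie algorithm), and while
ON initiates transcripts as a Poisson process at ``loading_rate``. Each
nascent transcript contributes a unit boxcar of signal for ``dwell_time``
seconds — the time the transcript (with its stem-loop array bound by
coat protein) resides at the transcription site. The observable trace at
a frame time is therefore the number of transcripts initiated within the
trailing ``dwell_time`` window, i.e. an M/D/infinity queue driven by the
telegraph process.

Rendering places non-overlapping disk-like nuclei (histone-marker
channel) that drift by a reflected random walk, and, for each nucleus
with nonzero trace, an elliptical Gaussian diffraction-limited spot
(spot channel) whose background-subtracted integral equals the trace
value before noise. Shot noise (Poisson) and Gaussian read noise are
optional. Everything drawn from one seeded generator; the ground truth
(positions, labels, traces, ON intervals) is recorded exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ms2burst.movie import MovieStack, write_movie


@dataclass
class TelegraphParams:
    """Two-state promoter kinetics.

    Parameters
    ----------
    k_on
        OFF -> ON switching rate (1/s). ``k_on = 0`` gives a never-ON
        control; all other rates must be strictly positive.
    k_off
        ON -> OFF switching rate (1/s).
    loading_rate
        Transcript initiation rate while ON (events/s).
    dwell_time
        Residence time of one nascent transcript's signal (s).
    seed
        RNG seed used when this parameter set is simulated standalone.
    """

    k_on: float
    k_off: float
    loading_rate: float
    dwell_time: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_on < 0:
            raise ValueError("k_on must be >= 0")
        if self.k_off <= 0 or self.loading_rate <= 0 or self.dwell_time <= 0:
            raise ValueError(
                "k_off, loading_rate and dwell_time must be strictly positive"
            )


@dataclass
class NoiseModel:
    """Shot + read noise. ``enabled=False`` renders noise-free images."""

    enabled: bool = True
    poisson_gain: float = 1.0
    read_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.poisson_gain <= 0:
            raise ValueError("poisson_gain must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")


@dataclass
class SceneConfig:
    """Everything needed to lay out and render one imaging condition."""

    n_nuclei: int = 50
    frame_count: int = 200
    frame_interval: float = 16.8
    image_shape: tuple[int, int, int] = (3, 220, 300)  # (z, rows, cols)
    nucleus_radius: float = 8.0
    drift_sigma: float = 0.5
    psf_sigma: tuple[float, float] = (1.5, 1.5)  # (sigma_y, sigma_x) px
    background_level: float = 100.0
    nuclei_level: float = 2000.0
    spot_unit_intensity: float = 200.0  # intensity integral per nascent transcript
    spot_offset: tuple[float, float] = (2.3, 1.7)  # spot centre rel. nucleus centroid
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    telegraph: TelegraphParams = field(
        default_factory=lambda: TelegraphParams(
            k_on=1 / 120.0, k_off=1 / 90.0, loading_rate=1 / 6.0, dwell_time=140.0
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0 or self.frame_count < 1:
            raise ValueError("need n_nuclei >= 0 and frame_count >= 1")
        if self.drift_sigma < 0:
            raise ValueError("drift_sigma must be >= 0")
        if len(self.image_shape) != 3:
            raise ValueError("image_shape is (z, rows, cols)")


@dataclass
class TelegraphTrace:
    """One simulated promoter trajectory sampled at frame times."""

    trace: np.ndarray  # transcripts at site per frame
    on_intervals: list[tuple[int, int]]  # inclusive frame-index pairs
    on_periods_s: list[tuple[float, float]]  # exact ON periods in seconds
    event_times: np.ndarray  # initiation times (s)


@dataclass
class GroundTruth:
    """Simulator-emitted truth for every nucleus and frame.

    ``labels`` are stable across frames (label i <-> nucleus i). Traces
    are in rendered intensity units (transcript count x unit intensity).
    """

    labels: np.ndarray  # (n,), stable positive ints
    centroids: np.ndarray  # (frames, n, 2) true (row, col)
    traces: np.ndarray  # (n, frames) intensity units
    on_intervals: list[list[tuple[int, int]]]  # per nucleus
    spot_positions: np.ndarray  # (frames, n, 2) subpixel (row, col)

    def nuclei_table(self) -> pd.DataFrame:
        frames, n, _ = self.centroids.shape
        rows = [
            (t, int(self.labels[i]), self.centroids[t, i, 0], self.centroids[t, i, 1])
            for t in range(frames)
            for i in range(n)
        ]
        return pd.DataFrame(rows, columns=["frame", "label", "y", "x"])

    def trace_table(self) -> pd.DataFrame:
        n, frames = self.traces.shape
        rows = [
            (int(self.labels[i]), t, self.traces[i, t])
            for i in range(n)
            for t in range(frames)
        ]
        return pd.DataFrame(rows, columns=["label", "frame", "value"])

    def bursts_table(self) -> pd.DataFrame:
        rows = [
            (int(self.labels[i]), s, e)
            for i, ivs in enumerate(self.on_intervals)
            for (s, e) in ivs
        ]
        return pd.DataFrame(rows, columns=["label", "start_frame", "end_frame"])


def simulate_telegraph(
    params: TelegraphParams,
    frame_count: int,
    frame_interval: float,
    rng: np.random.Generator | None = None,
    initial_on: bool | None = None,
) -> TelegraphTrace:
    """Exact continuous-time simulation of the telegraph promoter.

    The promoter state is simulated by the Gillespie algorithm
    (exponential holding times); initiation events while ON form a
    Poisson process at ``loading_rate``. The trace at frame ``t`` is the
    number of initiations in the window ``(t*dt - dwell_time, t*dt]``.

    Parameters
    ----------
    initial_on
        Force the initial promoter state; by default it is drawn from
        the chain's stationary distribution ``k_on / (k_on + k_off)``.
    """
    if frame_count < 1:
        raise ValueError("frame_count must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    total_time = (frame_count - 1) * frame_interval

    if params.k_on == 0:
        zero = np.zeros(frame_count)
        return TelegraphTrace(zero, [], [], np.empty(0))

    if initial_on is None:
        p_on = params.k_on / (params.k_on + params.k_off)
        state_on = bool(rng.random() < p_on)
    else:
        state_on = initial_on

    t = 0.0
    on_periods: list[tuple[float, float]] = []
    events: list[np.ndarray] = []
    while t <= total_time:
        rate = params.k_off if state_on else params.k_on
        hold = rng.exponential(1.0 / rate)
        t_end = min(t + hold, total_time + 1e-12)
        if state_on:
            on_periods.append((t, t_end))
            n_ev = rng.poisson(params.loading_rate * (t_end - t))
            if n_ev:
                events.append(np.sort(rng.uniform(t, t_end, n_ev)))
        t += hold
        state_on = not state_on

    event_times = np.concatenate(events) if events else np.empty(0)
    event_times.sort()

    frame_times = np.arange(frame_count) * frame_interval
    hi = np.searchsorted(event_times, frame_times, side="right")
    lo = np.searchsorted(event_times, frame_times - params.dwell_time, side="right")
    trace = (hi - lo).astype(float)

    # frames whose sample time falls inside an ON period, merged into runs
    on_frames = np.zeros(frame_count, dtype=bool)
    for a, b in on_periods:
        on_frames |= (frame_times >= a) & (frame_times <= b)
    on_intervals = _runs(on_frames)
    return TelegraphTrace(trace, on_intervals, on_periods, event_times)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, end) index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def _initial_layout(scene: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid placement with pairwise separation > 2 * radius."""
    _, n_rows, n_cols = scene.image_shape
    r = scene.nucleus_radius
    margin = r + 3.0
    pitch = 2 * r + 8.0  # grid pitch; jitter keeps edge gaps >= ~5 px
    usable_r = n_rows - 2 * margin
    usable_c = n_cols - 2 * margin
    grid_r = int(usable_r // pitch) + 1
    grid_c = int(usable_c // pitch) + 1
    if grid_r * grid_c < scene.n_nuclei:
        raise ValueError(
            f"image {n_rows}x{n_cols} cannot hold {scene.n_nuclei} nuclei "
            f"of radius {r} without overlap"
        )
    cells = [(i, j) for i in range(grid_r) for j in range(grid_c)]
    chosen = rng.choice(len(cells), size=scene.n_nuclei, replace=False)
    jitter_amp = max(0.0, (pitch - 2 * r) / 2 - 1.0)
    pos = np.empty((scene.n_nuclei, 2))
    for k, ci in enumerate(chosen):
        i, j = cells[ci]
        pos[k, 0] = margin + i * pitch + rng.uniform(-jitter_amp, jitter_amp)
        pos[k, 1] = margin + j * pitch + rng.uniform(-jitter_amp, jitter_amp)
    return pos


def _drift_positions(
    scene: SceneConfig, init: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Reflected random walk per nucleus; steps causing overlap are voided."""
    _, n_rows, n_cols = scene.image_shape
    r = scene.nucleus_radius
    lo = r + 1.0
    hi_r, hi_c = n_rows - r - 2.0, n_cols - r - 2.0
    min_sep = 2 * r + 4.0  # keep edge gaps wide enough to segment cleanly
    n = init.shape[0]
    out = np.empty((scene.frame_count, n, 2))
    out[0] = init
    for t in range(1, scene.frame_count):
        prev = out[t - 1]
        prop = prev + rng.normal(0.0, scene.drift_sigma, size=(n, 2))
        prop[:, 0] = _reflect(prop[:, 0], lo, hi_r)
        prop[:, 1] = _reflect(prop[:, 1], lo, hi_c)
        new = prev.copy()
        for i in range(n):
            cand = prop[i]
            others = np.vstack([new[:i], prev[i + 1 :]]) if n > 1 else np.empty((0, 2))
            if others.size == 0 or np.all(
                np.hypot(others[:, 0] - cand[0], others[:, 1] - cand[1]) >= min_sep
            ):
                new[i] = cand
        out[t] = new
    return out


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        raise ValueError("image too small for nucleus radius")
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def _disk_image(
    shape: tuple[int, int], centers: np.ndarray, radius: float, level: float
) -> np.ndarray:
    """Uniform disks with a soft 1-px edge, summed onto a blank image."""
    img = np.zeros(shape)
    rr = int(np.ceil(radius)) + 2
    for cy, cx in centers:
        y0, x0 = int(np.floor(cy)), int(np.floor(cx))
        ys = slice(max(0, y0 - rr), min(shape[0], y0 + rr + 1))
        xs = slice(max(0, x0 - rr), min(shape[1], x0 + rr + 1))
        yy, xx = np.mgrid[ys, xs]
        d = np.hypot(yy - cy, xx - cx)
        img[ys, xs] += level * np.clip(radius + 0.5 - d, 0.0, 1.0)
    return img


def _gaussian_spot(
    shape: tuple[int, int],
    center: tuple[float, float],
    sigma: tuple[float, float],
    integral: float,
) -> np.ndarray:
    """Elliptical Gaussian whose continuous integral is ``integral``."""
    sy, sx = sigma
    cy, cx = center
    amp = integral / (2 * np.pi * sy * sx)
    half = int(np.ceil(6 * max(sy, sx))) + 1
    y0, x0 = int(np.floor(cy)), int(np.floor(cx))
    ys = slice(max(0, y0 - half), min(shape[0], y0 + half + 1))
    xs = slice(max(0, x0 - half), min(shape[1], x0 + half + 1))
    yy, xx = np.mgrid[ys, xs]
    patch = amp * np.exp(
        -((yy - cy) ** 2 / (2 * sy**2) + (xx - cx) ** 2 / (2 * sx**2))
    )
    img = np.zeros(shape)
    img[ys, xs] = patch
    return img


def render_movie(
    traces: np.ndarray,
    scene: SceneConfig,
    on_intervals: list[list[tuple[int, int]]] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[MovieStack, GroundTruth]:
    """Render traces into a two-channel movie plus exact ground truth.

    Parameters
    ----------
    traces
        Array ``(n_nuclei, frame_count)`` of spot integrals (intensity
        units) per nucleus per frame — typically telegraph transcript
        counts already scaled by ``scene.spot_unit_intensity``.
    on_intervals
        Optional per-nucleus true ON intervals carried into the ground
        truth (empty lists if omitted).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape != (scene.n_nuclei, scene.frame_count):
        raise ValueError(
            f"traces shape {traces.shape} != (n_nuclei, frame_count) "
            f"= {(scene.n_nuclei, scene.frame_count)}"
        )
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    n_z, n_rows, n_cols = scene.image_shape
    mid_z = n_z // 2

    if scene.n_nuclei > 0:
        init = _initial_layout(scene, rng)
        centroids = _drift_positions(scene, init, rng)
    else:
        centroids = np.empty((scene.frame_count, 0, 2))

    offset = np.asarray(scene.spot_offset)
    spot_positions = centroids + offset

    nuc = np.zeros((scene.frame_count, n_z, n_rows, n_cols))
    ms2 = np.full((scene.frame_count, n_z, n_rows, n_cols), float(scene.background_level))
    nuc[:, :, :, :] = scene.background_level * 0.1
    for t in range(scene.frame_count):
        nuc[t, mid_z] += _disk_image(
            (n_rows, n_cols), centroids[t], scene.nucleus_radius, scene.nuclei_level
        )
        for i in range(scene.n_nuclei):
            v = traces[i, t]
            if v > 0:
                ms2[t, mid_z] += _gaussian_spot(
                    (n_rows, n_cols), tuple(spot_positions[t, i]), scene.psf_sigma, v
                )

    if scene.noise_model.enabled:
        g = scene.noise_model.poisson_gain
        nuc = rng.poisson(nuc * g) / g
        ms2 = rng.poisson(ms2 * g) / g
        sd = scene.noise_model.read_noise_sd
        if sd > 0:
            nuc = nuc + rng.normal(0.0, sd, nuc.shape)
            ms2 = ms2 + rng.normal(0.0, sd, ms2.shape)
        nuc = np.clip(nuc, 0.0, None)
        ms2 = np.clip(ms2, 0.0, None)

    movie = MovieStack(
        ms2_channel=ms2,
        nuclei_channel=nuc,
        frame_interval=scene.frame_interval,
    )
    truth = GroundTruth(
        labels=np.arange(1, scene.n_nuclei + 1),
        centroids=centroids,
        traces=traces,
        on_intervals=on_intervals
        if on_intervals is not None
        else [[] for _ in range(scene.n_nuclei)],
        spot_positions=spot_positions,
    )
    return movie, truth


def simulate_scene(scene: SceneConfig) -> tuple[MovieStack, GroundTruth]:
    """Simulate telegraph traces for every nucleus and render the movie.

    All randomness (kinetics, layout, drift, noise) derives from
    ``scene.seed`` through one spawned seed sequence, so identical
    configs give identical movies and ground truth.
    """
    ss = np.random.SeedSequence(scene.seed)
    children = ss.spawn(scene.n_nuclei + 1)
    render_rng = np.random.default_rng(children[0])
    traces = np.zeros((scene.n_nuclei, scene.frame_count))
    on_intervals: list[list[tuple[int, int]]] = []
    for i in range(scene.n_nuclei):
        res = simulate_telegraph(
            scene.telegraph,
            scene.frame_count,
            scene.frame_interval,
            rng=np.random.default_rng(children[i + 1]),
        )
        traces[i] = res.trace * scene.spot_unit_intensity
        on_intervals.append(res.on_intervals)
    return render_movie(traces, scene, on_intervals=on_intervals, rng=render_rng)


def scene_to_dict(scene: SceneConfig) -> dict:
    d = asdict(scene)
    d["image_shape"] = list(scene.image_shape)
    d["psf_sigma"] = list(scene.psf_sigma)
    d["spot_offset"] = list(scene.spot_offset)
    return d


def scene_from_dict(d: dict) -> SceneConfig:
    d = dict(d)
    known = set(SceneConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown scene config keys: {sorted(unknown)}")
    if "noise_model" in d and isinstance(d["noise_model"], dict):
        d["noise_model"] = NoiseModel(**d["noise_model"])
    if "telegraph" in d and isinstance(d["telegraph"], dict):
        d["telegraph"] = TelegraphParams(**d["telegraph"])
    for key in ("image_shape", "psf_sigma", "spot_offset"):
        if key in d:
            d[key] = tuple(d[key])
    return SceneConfig(**d)


def make_fixture(scene: SceneConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate a scene and write movies, ground truth and config to disk.

    Writes ``ms2.tif`` / ``nuclei.tif`` (multi-page 16-bit TIFF,
    frames-major), ``nuclei_truth.tsv``, ``trace_truth.tsv``,
    ``bursts_truth.tsv`` and the resolved ``scene.yaml``. Deterministic
    given ``scene.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    movie, truth = simulate_scene(scene)
    paths = {
        "ms2": out / "ms2.tif",
        "nuclei": out / "nuclei.tif",
        "nuclei_truth": out / "nuclei_truth.tsv",
        "trace_truth": out / "trace_truth.tsv",
        "bursts_truth": out / "bursts_truth.tsv",
        "config": out / "scene.yaml",
    }
    write_movie(movie, paths["ms2"], paths["nuclei"])
    truth.nuclei_table().to_csv(paths["nuclei_truth"], sep="\t", index=False)
    truth.trace_table().to_csv(paths["trace_truth"], sep="\t", index=False)
    truth.bursts_table().to_csv(paths["bursts_truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(scene_to_dict(scene), fh, sort_keys=False)
    return paths
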