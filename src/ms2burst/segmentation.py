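"""Per-frame nuclei segmentation from the histone-marker channel.

The chain per frame is: maximum z-projection, optional edge crop,
Gaussian blur plus bright-tail suppression, threshold-adaptive
binarization (scored by connected-component count and size), dot-aware
boundary correction so every transcription dot falls inside a nucleus,
and a Voronoi partition of the frame that bounds each nucleus's
measurement territory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.filters import threshold_otsu
from skimage.segmentation import find_boundaries

from ms2burst.movie import MovieStack

logger = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    """Tunable parameters of the segmentation chain.

    ``bright_removal`` selects how "bright pixel removal" is applied:
    ``"percentile"`` clips the brightest ``bright_tail_fraction`` of
    pixels to the cutoff quantile; ``"absolute"`` clips at
    ``(1 - bright_tail_fraction) * image max``.
    """

    blur_sigma: float = 1.5
    bright_tail_fraction: float = 0.05
    bright_removal: str = "percentile"  # or "absolute"
    expected_count: tuple[int, int] = (1, 5000)
    size_bounds: tuple[int, int] = (30, 5000)
    crop_box: tuple[int, int, int, int] | None = None
    min_size: int = 30  # components below this are discarded pre-Voronoi
    attach_ms2_dots: bool = True
    mask_override: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.bright_tail_fraction < 1):
            raise ValueError("bright_tail_fraction must be in [0, 1)")
        if self.bright_removal not in ("percentile", "absolute"):
            raise ValueError("bright_removal must be 'percentile' or 'absolute'")
        if self.expected_count[0] > self.expected_count[1]:
            raise ValueError("expected_count min > max")
        if self.size_bounds[0] > self.size_bounds[1]:
            raise ValueError("size_bounds min > max")


@dataclass
class LabeledFrame:
    """Segmentation result for one frame.

    ``labels`` is the nuclear mask (0 = background, positive integers =
    nuclei); ``territories`` assigns *every* pixel to the nearest
    nucleus centroid (Voronoi cell) and is the outer bound of each
    nucleus's measurement territory. Centroids are 0-based (row, col)
    pixel-center coordinates.
    """

    frame_index: int
    labels: np.ndarray
    territories: np.ndarray
    centroids: dict[int, tuple[float, float]]
    areas: dict[int, int]
    degraded: bool = False
    threshold: float = float("nan")

    @property
    def region_labels(self) -> list[int]:
        return sorted(self.centroids)

    def boundary_pixels(self, label: int) -> np.ndarray:
        """(k, 2) array of the region's inner-boundary pixel coords."""
        mask = self.labels == label
        bnd = find_boundaries(mask, mode="inner")
        return np.argwhere(bnd)


def max_project(stack_frame: np.ndarray) -> np.ndarray:
    """Maximum projection of a 3-D z-stack along z."""
    stack_frame = np.asarray(stack_frame)
    if stack_frame.ndim != 3 or stack_frame.shape[0] < 1:
        raise ValueError("need a 3-D (z, row, col) stack with >= 1 plane")
    return stack_frame.max(axis=0)


def crop_frame(image: np.ndarray, crop_box: tuple[int, int, int, int]) -> np.ndarray:
    """Extract the half-open sub-image ``(row0, col0, rows, cols)``."""
    image = np.asarray(image)
    row0, col0, rows, cols = crop_box
    if rows <= 0 or cols <= 0:
        raise ValueError("crop box must have positive extent")
    if row0 < 0 or col0 < 0 or row0 + rows > image.shape[0] or col0 + cols > image.shape[1]:
        raise ValueError(f"crop box {crop_box} outside image {image.shape}")
    return image[row0 : row0 + rows, col0 : col0 + cols]


def centered_crop_box(
    image_shape: tuple[int, int], out_shape: tuple[int, int] = (300, 430)
) -> tuple[int, int, int, int]:
    """Centered crop box of ``out_shape`` — the default edge trim that
    takes a 512x512 projection down to 300x430."""
    r0 = (image_shape[0] - out_shape[0]) // 2
    c0 = (image_shape[1] - out_shape[1]) // 2
    if r0 < 0 or c0 < 0:
        raise ValueError("crop larger than image")
    return (r0, c0, out_shape[0], out_shape[1])


def preprocess_nuclei(
    image: np.ndarray,
    blur_sigma: float = 1.5,
    bright_tail_fraction: float = 0.05,
    mode: str = "percentile",
) -> np.ndarray:
    """Gaussian blur followed by bright-pixel suppression.

    The brightest pixels — either the top ``bright_tail_fraction``
    quantile (default) or, in ``"absolute"`` mode, pixels above
    ``(1 - fraction) * max`` — are clipped to the cutoff value.
    Clipping rather than zeroing avoids punching holes in nuclei.
    """
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    if not (0 <= bright_tail_fraction < 1):
        raise ValueError("bright_tail_fraction must be in [0, 1)")
    img = np.asarray(image, dtype=float)
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma)
    if bright_tail_fraction > 0:
        if mode == "percentile":
            cutoff = np.quantile(img, 1.0 - bright_tail_fraction)
        elif mode == "absolute":
            cutoff = (1.0 - bright_tail_fraction) * img.max()
        else:
            raise ValueError("mode must be 'percentile' or 'absolute'")
        img = np.minimum(img, cutoff)
    return img


def adaptive_threshold(
    image: np.ndarray,
    expected_count: tuple[int, int],
    size_bounds: tuple[int, int],
) -> tuple[np.ndarray, float, bool]:
    """Threshold-adaptive binarization.

    Candidate thresholds are the 5th-95th percentiles of the image in
    1-percentile steps. Each candidate is scored by two indicators:
    connected-component count within ``expected_count`` and median
    component area within ``size_bounds`` (components below the size
    minimum are ignored). Ties break toward the candidate nearest
    Otsu's threshold. Returns ``(mask, threshold, degraded)`` where
    ``degraded`` flags frames where no candidate met both conditions.
    """
    if expected_count[0] > expected_count[1] or size_bounds[0] > size_bounds[1]:
        raise ValueError("expected_count / size_bounds must satisfy min <= max")
    img = np.asarray(image, dtype=float)
    if img.size == 0 or img.max() == img.min():
        return np.zeros(img.shape, dtype=bool), float("nan"), True

    candidates = np.unique(np.percentile(img, np.arange(5, 96)))
    otsu = threshold_otsu(img)
    best = None  # (score, -|thr - otsu|, thr, mask)
    for thr in candidates:
        mask = img > thr
        labels, n = ndimage.label(mask)
        if n == 0:
            score, count, med = 0, 0, 0.0
        else:
            areas = np.bincount(labels.ravel())[1:]
            areas = areas[areas >= size_bounds[0]]
            count = areas.size
            med = float(np.median(areas)) if count else 0.0
            score = int(expected_count[0] <= count <= expected_count[1]) + int(
                count > 0 and size_bounds[0] <= med <= size_bounds[1]
            )
        key = (score, -abs(thr - otsu))
        if best is None or key > best[0]:
            best = (key, thr, mask)
    (score, _), thr, mask = best
    return mask, float(thr), score < 2


def detect_ms2_dots(ms2_projection: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Transcription-dot detection on the spot-channel projection.

    A pixel belongs to a dot when its intensity exceeds twice the frame
    mean. Returns the boolean mask and an ``(n, 2)`` array of
    connected-component centroids (row, col).
    """
    img = np.asarray(ms2_projection, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    mask = img > 2.0 * img.mean()
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask, np.empty((0, 2))
    centroids = np.asarray(ndimage.center_of_mass(mask, labels, np.arange(1, n + 1)))
    return mask, centroids


def attach_dots(labels: np.ndarray, dots: np.ndarray) -> np.ndarray:
    """Modify nucleus boundaries so every dot lies inside a nucleus.

    For a dot centroid outside all regions, the region with the nearest
    boundary pixel (Euclidean; ties to the lower label) is dilated along
    the straight pixel path from that boundary pixel to the dot. Only
    background pixels are written, so regions stay pairwise disjoint.
    """
    labels = np.asarray(labels)
    out = labels.copy()
    dots = np.asarray(dots, dtype=float).reshape(-1, 2)
    if dots.shape[0] == 0:
        return out
    if out.max() == 0:
        logger.warning("attach_dots: no nuclei in frame; %d dots left unassigned", len(dots))
        return out

    bnd_mask = find_boundaries(out > 0, mode="inner")
    bnd_coords = np.argwhere(bnd_mask)
    bnd_labels = out[bnd_coords[:, 0], bnd_coords[:, 1]]
    # stable ordering so the nearest-with-lowest-label tie rule is exact
    order = np.lexsort((bnd_coords[:, 1], bnd_coords[:, 0], bnd_labels))
    bnd_coords = bnd_coords[order]
    bnd_labels = bnd_labels[order]

    nr, nc = out.shape
    for dy, dx in dots:
        py = int(np.clip(np.rint(dy), 0, nr - 1))
        px = int(np.clip(np.rint(dx), 0, nc - 1))
        if out[py, px] > 0:
            continue
        d2 = (bnd_coords[:, 0] - dy) ** 2 + (bnd_coords[:, 1] - dx) ** 2
        best = int(np.argmin(d2))  # first minimum = lowest label by ordering
        lab = int(bnd_labels[best])
        by, bx = int(bnd_coords[best, 0]), int(bnd_coords[best, 1])
        rr, cc = draw_line(by, bx, py, px)
        path_bg = out[rr, cc] == 0
        out[rr[path_bg], cc[path_bg]] = lab
        # widen the terminal pixel slightly so the dot is robustly inside
        for oy in (-1, 0, 1):
            for ox in (-1, 0, 1):
                qy, qx = py + oy, px + ox
                if 0 <= qy < nr and 0 <= qx < nc and out[qy, qx] == 0:
                    out[qy, qx] = lab
    return out


def voronoi_partition(
    centroids: np.ndarray,
    image_shape: tuple[int, int],
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Assign every pixel to its nearest centroid (Euclidean).

    ``labels`` supplies the output value per centroid (defaults to
    ``1..n``). Ties go to the centroid appearing first, i.e. the lower
    label when centroids are passed in label order.
    """
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if centroids.shape[0] == 0:
        raise ValueError("voronoi_partition requires >= 1 centroid")
    if labels is None:
        labels = np.arange(1, centroids.shape[0] + 1)
    labels = np.asarray(labels)
    nr, nc = image_shape
    yy, xx = np.mgrid[0:nr, 0:nc]
    best_d2 = np.full((nr, nc), np.inf)
    assign = np.zeros((nr, nc), dtype=labels.dtype)
    for (cy, cx), lab in zip(centroids, labels):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        better = d2 < best_d2  # strict: ties keep the earlier (lower) label
        best_d2[better] = d2[better]
        assign[better] = lab
    return assign


def _frame_regions(labels: np.ndarray) -> tuple[dict, dict]:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return {}, {}
    coms = ndimage.center_of_mass(labels > 0, labels, ids)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, ids)
    return (
        {int(i): (float(c[0]), float(c[1])) for i, c in zip(ids, coms)},
        {int(i): int(a) for i, a in zip(ids, areas)},
    )


def segment_frame(
    nuc_projection: np.ndarray,
    ms2_projection: np.ndarray | None,
    config: SegmentationConfig,
    frame_index: int = 0,
    override: np.ndarray | None = None,
) -> LabeledFrame:
    """Run the full per-frame chain and package the result."""
    if override is not None:
        labels = np.asarray(override).astype(np.int32)
        degraded, thr = False, float("nan")
    else:
        pre = preprocess_nuclei(
            nuc_projection,
            config.blur_sigma,
            config.bright_tail_fraction,
            config.bright_removal,
        )
        mask, thr, degraded = adaptive_threshold(
            pre, config.expected_count, config.size_bounds
        )
        labels, _ = ndimage.label(mask)
        if config.min_size > 0 and labels.max() > 0:
            areas = np.bincount(labels.ravel())
            small = np.flatnonzero(areas < config.min_size)
            labels[np.isin(labels, small[small > 0])] = 0
            labels, _ = ndimage.label(labels > 0)
        labels = labels.astype(np.int32)
        if config.attach_ms2_dots and ms2_projection is not None and labels.max() > 0:
            _, dots = detect_ms2_dots(ms2_projection)
            labels = attach_dots(labels, dots)

    centroids, areas = _frame_regions(labels)
    if centroids:
        ids = sorted(centroids)
        territories = voronoi_partition(
            np.array([centroids[i] for i in ids]), labels.shape, np.array(ids)
        )
    else:
        territories = np.zeros_like(labels)
        degraded = True
    return LabeledFrame(
        frame_index=frame_index,
        labels=labels,
        territories=territories,
        centroids=centroids,
        areas=areas,
        degraded=degraded,
        threshold=thr,
    )


def segment_movie(
    movie: MovieStack, config: SegmentationConfig | None = None
) -> list[LabeledFrame]:
    """Segment every frame of a movie.

    If ``config.crop_box`` is set, both channel projections are cropped
    before segmentation; downstream coordinates are then relative to the
    cropped frame (crop the movie identically before trace extraction).
    A mask override (label image) can be supplied per frame in place of
    the automatic result — the hook for externally curated masks.
    """
    if config is None:
        config = SegmentationConfig()
    out: list[LabeledFrame] = []
    for t in range(movie.n_frames):
        try:
            nuc = max_project(movie.nuclei_channel[t])
            ms2 = max_project(movie.ms2_channel[t])
            if config.crop_box is not None:
                nuc = crop_frame(nuc, config.crop_box)
                ms2 = crop_frame(ms2, config.crop_box)
            lf = segment_frame(
                nuc, ms2, config, frame_index=t, override=config.mask_override.get(t)
            )
        except Exception as exc:  # annotate with the failing frame
            raise RuntimeError(f"segmentation failed at frame {t}: {exc}") from exc
        if lf.degraded:
            logger.warning("frame %d: degraded segmentation (%d regions)", t, len(lf.centroids))
        out.append(lf)
    return out


def write_labeled_frames(frames: list[LabeledFrame], out_dir) -> None:
    """Write label and territory images as multi-page TIFFs plus QC."""
    from pathlib import Path

    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = np.stack([f.labels.astype(np.uint16) for f in frames])
    terr = np.stack([f.territories.astype(np.uint16) for f in frames])
    tifffile.imwrite(str(out / "labels.tif"), labels)
    tifffile.imwrite(str(out / "territories.tif"), terr)
    qc_table(frames).to_csv(out / "segmentation_qc.tsv", sep="\t", index=False)


def read_labeled_frames(seg_dir) -> list[LabeledFrame]:
    """Rebuild labeled frames from a directory written by write_labeled_frames."""
    from pathlib import Path

    import pandas as pd
    import tifffile

    seg = Path(seg_dir)
    labels = tifffile.imread(str(seg / "labels.tif"))
    terr = tifffile.imread(str(seg / "territories.tif"))
    if labels.ndim == 2:
        labels, terr = labels[None], terr[None]
    qc = pd.read_csv(seg / "segmentation_qc.tsv", sep="\t")
    frames = []
    for t in range(labels.shape[0]):
        lab = labels[t].astype(np.int32)
        centroids, areas = _frame_regions(lab)
        row = qc[qc["frame"] == t]
        frames.append(
            LabeledFrame(
                frame_index=t,
                labels=lab,
                territories=terr[t].astype(np.int32),
                centroids=centroids,
                areas=areas,
                degraded=bool(row["degraded"].iloc[0]) if len(row) else False,
                threshold=float(row["threshold"].iloc[0]) if len(row) else float("nan"),
            )
        )
    return frames


def qc_table(frames: list[LabeledFrame]):
    """Per-frame QC summary (region count, threshold, degraded flag)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "frame": [f.frame_index for f in frames],
            "n_regions": [len(f.centroids) for f in frames],
            "threshold": [f.threshold for f in frames],
            "degraded": [f.degraded for f in frames],
        }
    )
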