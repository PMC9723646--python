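"""Two-channel movie container and TIFF round-tripping.

A movie is a pair of aligned 4-D arrays ``(frame, z, row, col)``: one
channel carrying the nascent-transcription spots (MCP-GFP-like) and one
carrying the nuclear marker used for segmentation (His2Av-like), plus the
physical metadata needed to convert frames to seconds and pixels to
micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class MovieStack:
    """Aligned two-channel 4-D intensity arrays with physical metadata.

    Attributes
    ----------
    ms2_channel, nuclei_channel
        Arrays of shape ``(frames, z, rows, cols)``, non-negative,
        arbitrary intensity units. Both channels share one shape.
    frame_interval
        Seconds per frame.
    pixel_size
        Micrometers per pixel (xy).
    z_step
        Micrometers between z-planes.
    """

    ms2_channel: np.ndarray
    nuclei_channel: np.ndarray
    frame_interval: float = 16.8
    pixel_size: float = 0.2
    z_step: float = 0.5

    def __post_init__(self) -> None:
        self.ms2_channel = np.asarray(self.ms2_channel)
        self.nuclei_channel = np.asarray(self.nuclei_channel)
        if self.ms2_channel.ndim != 4:
            raise ValueError(
                f"channels must be 4-D (frame, z, row, col); got {self.ms2_channel.ndim}-D"
            )
        if self.ms2_channel.shape != self.nuclei_channel.shape:
            raise ValueError(
                "channel shapes differ: "
                f"{self.ms2_channel.shape} vs {self.nuclei_channel.shape}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.ms2_channel.size and (
            self.ms2_channel.min() < 0 or self.nuclei_channel.min() < 0
        ):
            raise ValueError("intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.ms2_channel.shape[0]

    @property
    def n_z(self) -> int:
        return self.ms2_channel.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.ms2_channel.shape[2:4]

    def crop(self, crop_box: tuple[int, int, int, int]) -> "MovieStack":
        """Crop both channels to ``(row0, col0, rows, cols)`` (half-open)."""
        row0, col0, rows, cols = crop_box
        nr, nc = self.frame_shape
        if row0 < 0 or col0 < 0 or row0 + rows > nr or col0 + cols > nc:
            raise ValueError(f"crop box {crop_box} outside frame shape {(nr, nc)}")
        return replace(
            self,
            ms2_channel=self.ms2_channel[:, :, row0 : row0 + rows, col0 : col0 + cols],
            nuclei_channel=self.nuclei_channel[
                :, :, row0 : row0 + rows, col0 : col0 + cols
            ],
        )


def write_movie(movie: MovieStack, ms2_path: str | Path, nuclei_path: str | Path) -> None:
    """Write each channel as a frames-major multi-page 16-bit TIFF."""
    for arr, path in (
        (movie.ms2_channel, ms2_path),
        (movie.nuclei_channel, nuclei_path),
    ):
        data = np.clip(np.rint(arr), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(
            str(path),
            data,
            metadata={
                "axes": "TZYX",
                "frame_interval_s": movie.frame_interval,
                "pixel_size_um": movie.pixel_size,
                "z_step_um": movie.z_step,
            },
        )


def read_movie(
    ms2_path: str | Path,
    nuclei_path: str | Path,
    frame_interval: float | None = None,
    pixel_size: float | None = None,
    z_step: float | None = None,
) -> MovieStack:
    """Read a two-channel movie written by :func:`write_movie`.

    Metadata stored in the TIFF is used unless overridden by arguments.
    A 3-D file (single z-plane) is promoted to shape ``(frames, 1, r, c)``.
    """
    arrays = []
    meta: dict = {}
    for path in (ms2_path, nuclei_path):
        with tifffile.TiffFile(str(path)) as tf:
            arr = tf.asarray()
            md = tf.shaped_metadata
            if md:
                meta.update(md[0])
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[:, None]
        elif arr.ndim != 4:
            raise ValueError(f"{path}: expected 2-4 dims, got {arr.ndim}")
        arrays.append(arr)
    return MovieStack(
        ms2_channel=arrays[0],
        nuclei_channel=arrays[1],
        frame_interval=frame_interval
        if frame_interval is not None
        else float(meta.get("frame_interval_s", 16.8)),
        pixel_size=pixel_size
        if pixel_size is not None
        else float(meta.get("pixel_size_um", 0.2)),
        z_step=z_step if z_step is not None else float(meta.get("z_step_um", 0.5)),
    )
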