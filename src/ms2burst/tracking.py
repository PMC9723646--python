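"""Nearest-centroid lineage tracking of segmented nuclei.

Links nuclei across consecutive frames by minimum centroid displacement:
candidate pairs are taken greedily in ascending distance order, each
nucleus matched at most once, and pairs farther apart than
``max_displacement`` are left unmatched (the track ends / a new track
starts). No gap closing: a missed detection terminates the track. In the
blastoderm-stage regime this targets — slow drift, no divisions within
the analysis window — per-frame displacement is far below inter-nucleus
spacing and the greedy rule coincides with the optimal assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ms2burst.segmentation import LabeledFrame


@dataclass
class TrackTable:
    """Long-format track assignments plus per-track extent.

    ``table`` has columns (frame, label, track_id, centroid_row,
    centroid_col) sorted by (track_id, frame); each track occupies
    consecutive frames and no two labels of one frame share a track.
    """

    table: pd.DataFrame
    min_length_flagged: set[int]

    @property
    def track_ids(self) -> list[int]:
        return sorted(self.table["track_id"].unique())

    def track_span(self, track_id: int) -> tuple[int, int]:
        frames = self.table.loc[self.table["track_id"] == track_id, "frame"]
        return int(frames.min()), int(frames.max())

    def label_at(self, track_id: int, frame: int) -> int | None:
        sel = self.table[
            (self.table["track_id"] == track_id) & (self.table["frame"] == frame)
        ]
        return int(sel["label"].iloc[0]) if len(sel) else None

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def link_frames(
    prev_centroids: np.ndarray,
    curr_centroids: np.ndarray,
    max_displacement: float,
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of centroid lists in ascending distance.

    Returns index pairs ``(i_prev, i_curr)``. Distance ties break toward
    the lower previous index, then lower current index. Pairs with
    distance > ``max_displacement`` are never formed.
    """
    if max_displacement <= 0:
        raise ValueError("max_displacement must be > 0")
    prev = np.asarray(prev_centroids, dtype=float).reshape(-1, 2)
    curr = np.asarray(curr_centroids, dtype=float).reshape(-1, 2)
    if prev.shape[0] == 0 or curr.shape[0] == 0:
        return []
    d = cdist(prev, curr)
    ii, jj = np.nonzero(d <= max_displacement)
    if ii.size == 0:
        return []
    order = np.lexsort((jj, ii, d[ii, jj]))
    used_prev = np.zeros(prev.shape[0], dtype=bool)
    used_curr = np.zeros(curr.shape[0], dtype=bool)
    pairs: list[tuple[int, int]] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if not used_prev[i] and not used_curr[j]:
            used_prev[i] = used_curr[j] = True
            pairs.append((i, j))
    return pairs


def track_movie(
    frames: list[LabeledFrame],
    max_displacement: float = 8.0,
    min_track_length: int = 1,
) -> TrackTable:
    """Assign stable track ids across a sequence of labeled frames."""
    if len(frames) == 0:
        raise ValueError("need >= 1 frame")
    rows: list[tuple[int, int, int, float, float]] = []
    next_track = 1
    prev_ids: list[int] = []
    prev_pts = np.empty((0, 2))
    prev_tracks: dict[int, int] = {}

    for lf in frames:
        ids = lf.region_labels
        pts = np.array([lf.centroids[i] for i in ids]).reshape(-1, 2)
        assignment: dict[int, int] = {}
        if prev_pts.shape[0] and pts.shape[0]:
            for ip, ic in link_frames(prev_pts, pts, max_displacement):
                assignment[ids[ic]] = prev_tracks[prev_ids[ip]]
        for lab in ids:
            if lab not in assignment:
                assignment[lab] = next_track
                next_track += 1
        for lab, (cy, cx) in ((i, lf.centroids[i]) for i in ids):
            rows.append((lf.frame_index, lab, assignment[lab], cy, cx))
        prev_ids, prev_pts, prev_tracks = ids, pts, assignment

    table = pd.DataFrame(
        rows, columns=["frame", "label", "track_id", "centroid_row", "centroid_col"]
    ).sort_values(["track_id", "frame"], ignore_index=True)
    lengths = table.groupby("track_id").size()
    flagged = set(lengths.index[lengths < min_track_length].astype(int))
    return TrackTable(table=table, min_length_flagged=flagged)
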