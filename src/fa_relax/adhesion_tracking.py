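"""Linking adhesion records into tracks; lifespans; peripheral/central classes.

Adhesions are near-stationary at 3-min sampling, so frame-to-frame linking
is greedy nearest-neighbor with a distance gate (default 1 µm) and a short
gap tolerance (default 1 missed frame).  Greedy order is fixed by
(distance, smaller label), making tracking fully deterministic.  A track's
death is operationalized as disappearance from segmentation for more than
``max_gap`` consecutive frames: the same min-area/threshold that defines a
detection therefore defines "complete disassembly" for synthetic and real
movies alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["AdhesionTrack", "link_tracks", "classify_location", "lifespan_table"]


@dataclass
class AdhesionTrack:
    """One adhesion followed across frames (half-open [birth_frame, death_frame))."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    intensities: list[float] = field(default_factory=list)
    location_class: str | None = None
    censored: bool = False  # still present in the movie's final frame

    @property
    def birth_frame(self) -> int:
        return self.frames[0]

    @property
    def death_frame(self) -> int:
        return self.frames[-1] + 1

    @property
    def mean_centroid(self) -> tuple[float, float]:
        arr = np.asarray(self.centroids)
        return float(arr[:, 0].mean()), float(arr[:, 1].mean())

    def alive_at(self, frame: int) -> bool:
        return self.birth_frame <= frame < self.death_frame

    def intensity_at(self, frame: int) -> float | None:
        """Background-subtracted total intensity at a frame.

        Returns None outside the track's life; gap frames inside the life
        are filled by linear interpolation between flanking detections.
        """
        if not self.alive_at(frame):
            return None
        if frame in self._index:
            return self.intensities[self._index[frame]]
        return float(np.interp(frame, self.frames, self.intensities))

    @property
    def _index(self) -> dict:
        if not hasattr(self, "_index_cache") or len(self._index_cache) != len(self.frames):
            self._index_cache = {f: i for i, f in enumerate(self.frames)}
        return self._index_cache


def link_tracks(
    records: pd.DataFrame,
    pixel_size: float,
    max_displacement_um: float = 1.0,
    max_gap_frames: int = 1,
) -> list[AdhesionTrack]:
    """Greedy nearest-neighbor linking of per-frame adhesion records.

    ``records`` needs columns frame, label, centroid_row, centroid_col and
    total_intensity (as produced by :func:`~fa_relax.adhesion_imaging.segment_movie`).
    Candidate (track, detection) pairs within the gate are assigned in
    ascending (distance, label) order; unmatched detections open new tracks;
    a track missing more than ``max_gap_frames`` consecutive frames is closed
    with death at its last detection + 1.
    """
    if len(records) == 0:
        return []
    records = records.sort_values(["frame", "label"])
    gate_px = max_displacement_um / pixel_size
    max_frame = int(records["frame"].max())

    tracks: list[AdhesionTrack] = []
    active: list[AdhesionTrack] = []
    next_id = 0
    for f, group in records.groupby("frame", sort=True):
        f = int(f)
        # retire tracks whose gap can no longer be closed
        still = []
        for tr in active:
            if f - tr.frames[-1] > max_gap_frames + 1:
                tracks.append(tr)
            else:
                still.append(tr)
        active = still

        dets = group.reset_index(drop=True)
        pairs = []
        for ti, tr in enumerate(active):
            r0, c0 = tr.centroids[-1]
            d = np.hypot(dets["centroid_row"] - r0, dets["centroid_col"] - c0)
            for di in np.nonzero(d.values <= gate_px)[0]:
                pairs.append((float(d.values[di]), int(dets["label"].iloc[di]), ti, int(di)))
        pairs.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, _label, ti, di in pairs:
            if ti in used_tracks or di in used_dets:
                continue
            used_tracks.add(ti)
            used_dets.add(di)
            tr = active[ti]
            row = dets.iloc[di]
            tr.frames.append(f)
            tr.labels.append(int(row["label"]))
            tr.centroids.append((float(row["centroid_row"]), float(row["centroid_col"])))
            tr.intensities.append(float(row["total_intensity"]))
        for di in range(len(dets)):
            if di in used_dets:
                continue
            row = dets.iloc[di]
            tr = AdhesionTrack(track_id=next_id)
            next_id += 1
            tr.frames.append(f)
            tr.labels.append(int(row["label"]))
            tr.centroids.append((float(row["centroid_row"]), float(row["centroid_col"])))
            tr.intensities.append(float(row["total_intensity"]))
            active.append(tr)
    for tr in active:
        tr.censored = tr.frames[-1] == max_frame
        tracks.append(tr)
    tracks.sort(key=lambda t: t.track_id)
    return tracks


def classify_location(
    track: AdhesionTrack, cell_mask: np.ndarray, peripheral_band: float = 0.25
) -> str:
    """Peripheral vs central by normalized distance from the cell boundary.

    d = distance transform / its in-mask maximum at the track's mean
    centroid; peripheral iff d ≤ ``peripheral_band``.
    """
    dist = ndimage.distance_transform_edt(cell_mask)
    peak = dist.max()
    dnorm = dist / peak if peak > 0 else dist
    r, c = track.mean_centroid
    ri = int(np.clip(round(r), 0, cell_mask.shape[0] - 1))
    ci = int(np.clip(round(c), 0, cell_mask.shape[1] - 1))
    if not cell_mask[ri, ci]:
        warnings.warn(f"track {track.track_id} centroid outside the cell mask; "
                      "classified by nearest boundary")
        cls = "peripheral"
    else:
        cls = "peripheral" if dnorm[ri, ci] <= peripheral_band else "central"
    track.location_class = cls
    return cls


def classify_all(tracks: list[AdhesionTrack], cell_mask: np.ndarray,
                 peripheral_band: float = 0.25) -> None:
    """Classify every track in place (shares one distance transform)."""
    dist = ndimage.distance_transform_edt(cell_mask)
    peak = dist.max()
    dnorm = dist / peak if peak > 0 else dist
    for tr in tracks:
        r, c = tr.mean_centroid
        ri = int(np.clip(round(r), 0, cell_mask.shape[0] - 1))
        ci = int(np.clip(round(c), 0, cell_mask.shape[1] - 1))
        if not cell_mask[ri, ci]:
            warnings.warn(f"track {tr.track_id} centroid outside the cell mask")
            tr.location_class = "peripheral"
        else:
            tr.location_class = "peripheral" if dnorm[ri, ci] <= peripheral_band else "central"


def lifespan_table(
    tracks: list[AdhesionTrack],
    frame_interval: float,
    drug_frame: int | None = None,
) -> pd.DataFrame:
    """One row per track: birth/death/lifespan in minutes plus class flags."""
    rows = []
    for tr in tracks:
        rows.append({
            "track_id": tr.track_id,
            "birth_min": tr.birth_frame * frame_interval,
            "death_min": tr.death_frame * frame_interval,
            "lifespan_min": (tr.death_frame - tr.birth_frame) * frame_interval,
            "location_class": tr.location_class,
            "alive_at_drug": tr.alive_at(drug_frame) if drug_frame is not None else None,
            "censored": tr.censored,
        })
    return pd.DataFrame(
        rows,
        columns=["track_id", "birth_min", "death_min", "lifespan_min",
                 "location_class", "alive_at_drug", "censored"],
    )
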