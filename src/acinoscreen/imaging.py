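"""Object detection, measurement and tracking for time-lapse fields.

Acini are segmented from the phase-proxy channel (Otsu threshold by
default), filtered on reporter positivity and border contact, measured
(size / shape / intensity), and linked frame-to-frame into tracks by
greedy nearest-centroid assignment with a displacement gate.  Track
fragments separated by short detection gaps are merged and short tracks
dropped, then everything is assembled into the flat per-object, per-frame
feature table the classifier and screen statistics consume.

Coordinates are 0-based pixel indices, x = column, y = row, origin
top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "DetectedObject",
    "Track",
    "segment_frame",
    "filter_objects",
    "measure_features",
    "link_tracks",
    "correct_tracks",
    "assemble_feature_table",
    "FEATURE_COLUMNS",
]

FORM_FACTOR_CAP = 1.1  # 1 + digitization epsilon

FEATURE_COLUMNS = [
    "area", "perimeter", "form_factor", "eccentricity", "solidity",
    "extent", "major_axis", "minor_axis", "intensity_c1", "intensity_c2",
]


@dataclass
class DetectedObject:
    field_id: str
    frame: int
    label: int
    centroid: tuple[float, float]        # (x, y)
    mask: np.ndarray                     # boolean, full-frame
    touches_border: bool
    reporter_mean: float
    features: dict = field(default_factory=dict)


@dataclass
class Track:
    track_id: int
    objects: list[DetectedObject]
    condition: str = ""
    replicate: int = 0

    @property
    def frames(self) -> list[int]:
        return [o.frame for o in self.objects]

    def validate(self) -> None:
        frames = self.frames
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing")


def measure_features(mask: np.ndarray, channels: np.ndarray) -> dict:
    """Geometry and intensity features on one object mask.

    ``channels`` is (C, H, W); integrated intensity is the sum of each
    channel over the mask.  Degenerate (single-pixel / zero-perimeter)
    masks get defined outputs: axis lengths 1, form factor capped at
    1 + 0.1.  Movement features are zero until tracking fills them.
    """
    if not mask.any():
        raise ValueError("mask is empty")
    props = regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    if perimeter > 0:
        form_factor = min(4 * np.pi * area / perimeter ** 2, FORM_FACTOR_CAP)
    else:
        form_factor = FORM_FACTOR_CAP
    major = float(props.axis_major_length) or 1.0
    minor = float(props.axis_minor_length) or 1.0
    features = {
        "area": area,
        "perimeter": perimeter,
        "form_factor": form_factor,
        "eccentricity": float(props.eccentricity),
        "solidity": float(props.solidity),
        "extent": float(props.extent),
        "major_axis": major,
        "minor_axis": minor,
    }
    channels = np.atleast_3d(channels)
    if channels.ndim == 2:
        channels = channels[None]
    for i in range(channels.shape[0]):
        features[f"intensity_c{i + 1}"] = float(channels[i][mask].sum())
    for i in range(channels.shape[0], 2):      # always expose two channels
        features[f"intensity_c{i + 1}"] = 0.0
    features["displacement"] = 0.0
    features["path_length"] = 0.0
    return features


def segment_frame(
    frame: np.ndarray,
    min_area: float = 25.0,
    threshold_method: str = "otsu",
    field_id: str = "",
    frame_index: int = 0,
) -> list[DetectedObject]:
    """Connected components of the thresholded phase-proxy channel.

    ``frame`` is (2, H, W): phase proxy then reporter.  Objects below
    ``min_area`` are discarded; each detection carries the mean reporter
    intensity over its mask and a border-contact flag.  A blank frame
    yields an empty list.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3 or frame.shape[0] < 1:
        raise ValueError("frame must be (n_channels, H, W)")
    phase = frame[0]
    reporter = frame[1] if frame.shape[0] > 1 else np.zeros_like(phase)
    if phase.size == 0:
        raise ValueError("empty grid")
    if phase.max() == phase.min():
        return []
    if threshold_method == "otsu":
        thresh = threshold_otsu(phase)
    else:
        try:
            thresh = float(threshold_method)
        except (TypeError, ValueError):
            raise ValueError(
                f"unknown threshold method {threshold_method!r}"
            ) from None
    binary = phase > thresh
    labels = cc_label(binary, connectivity=2)
    h, w = phase.shape
    detections = []
    for props in regionprops(labels):
        if props.area < min_area:
            continue
        mask = labels == props.label
        minr, minc, maxr, maxc = props.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        cy, cx = props.centroid
        detections.append(
            DetectedObject(
                field_id=field_id,
                frame=frame_index,
                label=int(props.label),
                centroid=(float(cx), float(cy)),
                mask=mask,
                touches_border=bool(touches),
                reporter_mean=float(reporter[mask].mean()),
                features=measure_features(mask, frame),
            )
        )
    return detections


def filter_objects(
    objects: list[DetectedObject],
    reporter_threshold: float = 0.0,
    exclude_border: bool = True,
) -> list[DetectedObject]:
    """Retain reporter-positive objects; drop border-touchers when asked.

    Order is stable.
    """
    kept = []
    for obj in objects:
        if obj.reporter_mean < reporter_threshold:
            continue
        if exclude_border and obj.touches_border:
            continue
        kept.append(obj)
    return kept


def link_tracks(
    objects_by_frame: dict[int, list[DetectedObject]],
    max_displacement: float = 50.0,
) -> list[Track]:
    """Greedy nearest-centroid frame-to-frame linking.

    Candidate links between consecutive frames are taken in order of
    centroid distance; links beyond ``max_displacement`` are rejected and
    unmatched objects start new tracks.  Displacement and cumulative path
    length are filled on every linked object.
    """
    frames = sorted(objects_by_frame)
    if frames and frames != list(range(frames[0], frames[-1] + 1)):
        raise ValueError("frames must be indexed consecutively")
    tracks: list[Track] = []
    active: dict[int, Track] = {}        # track_id -> Track (last frame current)
    next_id = 0
    prev_objects: list[tuple[int, DetectedObject]] = []
    for f in frames:
        current = objects_by_frame.get(f, [])
        assignments: dict[int, int] = {}  # current index -> track_id
        if prev_objects and current:
            pairs = []
            for tid, prev in prev_objects:
                px, py = prev.centroid
                for j, obj in enumerate(current):
                    ox, oy = obj.centroid
                    d = np.hypot(ox - px, oy - py)
                    if d <= max_displacement:
                        pairs.append((d, tid, j))
            pairs.sort(key=lambda t: (t[0], t[1], t[2]))
            used_tracks: set[int] = set()
            used_objects: set[int] = set()
            for d, tid, j in pairs:
                if tid in used_tracks or j in used_objects:
                    continue
                assignments[j] = tid
                used_tracks.add(tid)
                used_objects.add(j)
        new_prev = []
        for j, obj in enumerate(current):
            if j in assignments:
                track = active[assignments[j]]
                last = track.objects[-1]
                dx = obj.centroid[0] - last.centroid[0]
                dy = obj.centroid[1] - last.centroid[1]
                step = float(np.hypot(dx, dy))
                obj.features["displacement"] = step
                obj.features["path_length"] = (
                    last.features.get("path_length", 0.0) + step
                )
                track.objects.append(obj)
                new_prev.append((track.track_id, obj))
            else:
                track = Track(track_id=next_id, objects=[obj])
                obj.features["displacement"] = 0.0
                obj.features["path_length"] = 0.0
                tracks.append(track)
                active[next_id] = track
                new_prev.append((next_id, obj))
                next_id += 1
        prev_objects = new_prev
    return tracks


def correct_tracks(
    tracks: list[Track],
    max_gap: int = 2,
    gate: float = 50.0,
    min_length: int = 3,
) -> list[Track]:
    """Merge fragments across short gaps; drop short tracks.

    A fragment whose start lies within ``max_gap`` frames and ``gate``
    pixels of another fragment's end is appended to it; with two merge
    candidates the nearer centroid wins, ties by lowest track id.  Merged
    tracks re-derive displacement and path length; tracks shorter than
    ``min_length`` frames are removed.
    """
    fragments = sorted(tracks, key=lambda t: t.track_id)
    merged_into: dict[int, int] = {}
    by_id = {t.track_id: list(t.objects) for t in fragments}
    changed = True
    while changed:
        changed = False
        ids = sorted(by_id)
        for tid in ids:
            if tid not in by_id:
                continue
            objs = by_id[tid]
            end_frame = objs[-1].frame
            ex, ey = objs[-1].centroid
            best = None
            for oid in ids:
                if oid == tid or oid not in by_id:
                    continue
                cand = by_id[oid]
                gap = cand[0].frame - end_frame
                if not (1 <= gap <= max_gap + 1):
                    continue
                sx, sy = cand[0].centroid
                d = np.hypot(sx - ex, sy - ey)
                if d > gate:
                    continue
                if best is None or (d, oid) < (best[0], best[1]):
                    best = (d, oid)
            if best is not None:
                _, oid = best
                by_id[tid] = objs + by_id.pop(oid)
                merged_into[oid] = tid
                changed = True
                break
    out = []
    for tid, objs in sorted(by_id.items()):
        if len(objs) < min_length:
            continue
        track = Track(track_id=tid, objects=objs)
        # re-derive movement features across the merged sequence
        prev = None
        for obj in objs:
            if prev is None:
                obj.features["displacement"] = 0.0
                obj.features["path_length"] = 0.0
            else:
                step = float(np.hypot(obj.centroid[0] - prev.centroid[0],
                                      obj.centroid[1] - prev.centroid[1]))
                obj.features["displacement"] = step
                obj.features["path_length"] = (
                    prev.features["path_length"] + step
                )
            prev = obj
        track.validate()
        out.append(track)
    return out


TABLE_COLUMNS = [
    "object_id", "track_id", "frame", "condition", "replicate", "well",
    "field", "area", "perimeter", "form_factor", "eccentricity", "solidity",
    "extent", "major_axis", "minor_axis", "intensity_c1", "intensity_c2",
    "reporter_mean", "touches_border", "displacement", "path_length",
]


def assemble_feature_table(
    tracks: list[Track],
    metadata: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """One record per (track, frame), with well metadata joined.

    ``metadata`` maps field id -> ``{"condition": ..., "replicate": ...,
    "well": ..., "field": ...}``; a field with no metadata raises an error
    naming it.  The result round-trips losslessly through CSV.
    """
    records = []
    counter = 0
    for track in tracks:
        for obj in track.objects:
            if metadata is not None:
                meta = metadata.get(obj.field_id)
                if meta is None:
                    raise KeyError(
                        f"no metadata for field {obj.field_id!r}"
                    )
            else:
                meta = {"condition": "", "replicate": 0,
                        "well": "", "field": 0}
            row = {
                "object_id": counter,
                "track_id": track.track_id,
                "frame": obj.frame,
                "condition": meta["condition"],
                "replicate": meta["replicate"],
                "well": meta["well"],
                "field": meta["field"],
                **{k: obj.features[k] for k in FEATURE_COLUMNS},
                "reporter_mean": obj.reporter_mean,
                "touches_border": obj.touches_border,
                "displacement": obj.features["displacement"],
                "path_length": obj.features["path_length"],
            }
            records.append(row)
            counter += 1
    if not records:
        return pd.DataFrame(columns=TABLE_COLUMNS)
    return pd.DataFrame.from_records(records)[TABLE_COLUMNS]
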