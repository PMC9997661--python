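"""Synthetic inputs for every stage of the screen pipeline.

Emulated study conditions: per-well fields imaged hourly over 96 h (97
frames, two positions per well), heterogeneous acini that stay in or cycle
between the Round / Spindle / Spread morphology states under a first-order
Markov chain, mem:Venus reporter-positive and -negative objects,
condition-specific shifts in state frequencies with experimental-replicate
structure, logistic wound closure with single-cell / sheet / chain front
textures, and cells with nuclei plus two puncta channels with a planted
overlap fraction.  Every simulator is a pure function of its config
(including the seed), and ground truth is returned alongside the rendered
data so recovery can be tested.

Class archetypes are the module's own: Round is a near-circular ellipse
(axis ratio <= 1.2), Spindle an elongated ellipse (ratio 3.2-6), Spread an
ellipse with 3-8 thin radial protrusions that drop solidity below 0.8.
The bands are chosen so the three classes are separable by the measured
shape features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from . import CLASS_NAMES
from .wound_assay import WoundSeries

__all__ = [
    "ScreenSimConfig",
    "GroundTruthPlate",
    "WoundSimConfig",
    "PunctaSimConfig",
    "PunctaField",
    "CohortSimConfig",
    "PlacementError",
    "TRANSITION_CONTROL",
    "TRANSITION_SPREAD_2X",
    "markov_occupancy",
    "sample_state_trajectories",
    "render_acinus",
    "simulate_acinus_timelapse",
    "simulate_screen_counts",
    "simulate_wound_assay",
    "simulate_puncta_field",
    "simulate_cohort",
    "make_gaussian_classes",
]


class PlacementError(RuntimeError):
    """Objects could not be placed without overlap after bounded retries."""


#: Default hourly transition matrix of an unperturbed (control) well:
#: mostly-Round acini with occasional excursions to Spindle and Spread.
TRANSITION_CONTROL = np.array(
    [[0.96, 0.03, 0.01],
     [0.06, 0.92, 0.02],
     [0.02, 0.03, 0.95]]
)

#: Planted "2x Spread" effect: starting all-Round, the run-averaged Spread
#: occupancy over 97 hourly frames is 2.00x the control matrix's.
TRANSITION_SPREAD_2X = np.array(
    [[0.9472, 0.03, 0.0228],
     [0.06, 0.9072, 0.0328],
     [0.0136, 0.0236, 0.9628]]
)


def _check_row_stochastic(m, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"{name} must be 3x3")
    if (m < 0).any() or (m > 1).any():
        raise ValueError(f"{name} entries must be probabilities in [0, 1]")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError(f"{name} rows must sum to 1 within 1e-9")
    return m


@dataclass
class ScreenSimConfig:
    """Study conditions for the time-lapse acinus screen.

    Defaults mirror the screen design: hourly frames over 96 h (97 frames
    starting 4 h after plating), two imaging positions per well, three
    experimental replicates.
    """

    n_conditions: int = 2                       # including control
    n_replicates: int = 3
    wells_per_condition: int = 1
    fields_per_well: int = 2
    n_frames: int = 97
    objects_per_field: int = 12
    transition_matrix_control: np.ndarray = field(
        default_factory=lambda: TRANSITION_CONTROL.copy()
    )
    transition_matrix_per_condition: list[np.ndarray] | None = None
    replicate_jitter: float = 0.0
    reporter_positive_fraction: float = 1.0
    growth_rate: float = 0.01                   # relative area increase / h
    image_size: int = 256
    initial_area: float = 150.0                 # px^2 at frame 0
    initial_state_distribution: tuple[float, float, float] = (1.0, 0.0, 0.0)
    step_sd: float = 1.0                        # px centroid drift / frame
    noise_sd: float = 0.0                       # additive image noise
    control_name: str = "Scr"
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix_control = _check_row_stochastic(
            self.transition_matrix_control, "control transition matrix"
        )
        if self.transition_matrix_per_condition is None:
            self.transition_matrix_per_condition = [
                self.transition_matrix_control.copy()
                for _ in range(self.n_conditions - 1)
            ]
        self.transition_matrix_per_condition = [
            _check_row_stochastic(m, f"condition {i + 1} transition matrix")
            for i, m in enumerate(self.transition_matrix_per_condition)
        ]
        if len(self.transition_matrix_per_condition) != self.n_conditions - 1:
            raise ValueError(
                "need one transition matrix per non-control condition"
            )
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0 <= self.reporter_positive_fraction <= 1:
            raise ValueError("reporter_positive_fraction must be in [0, 1]")
        if self.replicate_jitter < 0:
            raise ValueError("replicate_jitter must be nonnegative")
        start = np.asarray(self.initial_state_distribution, dtype=float)
        if start.shape != (3,) or not np.isclose(start.sum(), 1.0, atol=1e-9):
            raise ValueError("initial_state_distribution must be a 3-simplex point")

    @property
    def condition_names(self) -> list[str]:
        return [self.control_name] + [
            f"cond{i + 1}" for i in range(self.n_conditions - 1)
        ]

    def matrix_for(self, condition: str) -> np.ndarray:
        if condition == self.control_name:
            return self.transition_matrix_control
        i = self.condition_names.index(condition) - 1
        return self.transition_matrix_per_condition[i]


@dataclass
class GroundTruthPlate:
    """Rendered fields plus the per-object, per-frame truth records."""

    frames: dict[tuple[str, int, int, int], np.ndarray]
    # key = (condition, replicate, well, field); value (n_frames, 2, H, W)
    truth_table: pd.DataFrame
    config: ScreenSimConfig


def markov_occupancy(
    transition: np.ndarray, start: np.ndarray, n_frames: int
) -> np.ndarray:
    """State occupancy per frame by matrix powers; shape (n_frames, 3)."""
    transition = np.asarray(transition, dtype=float)
    occ = np.empty((n_frames, 3))
    p = np.asarray(start, dtype=float)
    for t in range(n_frames):
        occ[t] = p
        p = p @ transition
    return occ


def sample_state_trajectories(
    transition: np.ndarray,
    start: np.ndarray,
    n_objects: int,
    n_frames: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """First-order Markov state paths; shape (n_objects, n_frames), int codes."""
    transition = np.asarray(transition, dtype=float)
    states = np.empty((n_objects, n_frames), dtype=int)
    states[:, 0] = rng.choice(3, size=n_objects, p=np.asarray(start))
    cum_rows = transition.cumsum(axis=1)
    for t in range(1, n_frames):
        u = rng.random(n_objects)
        states[:, t] = (u[:, None] > cum_rows[states[:, t - 1]]).sum(axis=1)
    return states


def _jitter_matrix(
    matrix: np.ndarray, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric Dirichlet perturbation of each row.

    Row' ~ Dirichlet(row / jitter) over the row's positive entries, so the
    expected row is unchanged and jitter -> 0 recovers the row exactly.
    Structural zeros are preserved.
    """
    if jitter == 0:
        return matrix.copy()
    out = np.zeros_like(matrix)
    for i, row in enumerate(matrix):
        pos = row > 0
        if pos.sum() == 1:
            out[i] = row
            continue
        alpha = row[pos] / jitter
        out[i, pos] = rng.dirichlet(alpha)
    return out


# ---------------------------------------------------------------------------
# rendering

_ROUND_RATIO = (1.0, 1.2)
_SPINDLE_RATIO = (3.2, 6.0)
_SPREAD_ARMS = (3, 8)


def render_acinus(
    cls: str,
    area: float,
    orientation: float,
    canvas: np.ndarray,
    center: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one acinus of the requested class and area onto ``canvas``.

    Returns the boolean mask of the drawn object (same shape as canvas);
    the canvas itself is modified in place (intensity 1 inside the mask).
    The drawn area is within 10% of the requested area.
    """
    if area < 25:
        raise ValueError("area must be >= 25 px^2")
    if canvas.ndim != 2:
        raise ValueError("canvas must be 2-D")
    h, w = canvas.shape
    if min(h, w) ** 2 < 4 * area:
        raise ValueError("canvas too small for requested area")
    rng = np.random.default_rng(0) if rng is None else rng
    if center is None:
        center = (h / 2, w / 2)
    cy, cx = center
    mask = np.zeros_like(canvas, dtype=bool)

    if cls == "Round":
        ratio = rng.uniform(*_ROUND_RATIO)
        b = np.sqrt(area / (np.pi * ratio))
        rr, cc = draw_ellipse(cy, cx, ratio * b, b,
                              shape=canvas.shape, rotation=orientation)
        mask[rr, cc] = True
    elif cls == "Spindle":
        ratio = rng.uniform(*_SPINDLE_RATIO)
        b = np.sqrt(area / (np.pi * ratio))
        rr, cc = draw_ellipse(cy, cx, ratio * b, b,
                              shape=canvas.shape, rotation=orientation)
        mask[rr, cc] = True
    elif cls == "Spread":
        n_arms = int(rng.integers(_SPREAD_ARMS[0], _SPREAD_ARMS[1] + 1))
        body_area = 0.80 * area
        radius = np.sqrt(body_area / np.pi)
        rr, cc = draw_ellipse(cy, cx, radius, radius, shape=canvas.shape)
        mask[rr, cc] = True
        arm_len = 2.2 * radius
        # arm width sized so the protrusions contribute the remaining ~20%
        arm_w = max(1.5, 0.20 * area / (n_arms * (arm_len - radius)))
        angles = orientation + 2 * np.pi * np.arange(n_arms) / n_arms
        angles = angles + rng.uniform(-0.2, 0.2, size=n_arms)
        for ang in angles:
            dy, dx = np.sin(ang), np.cos(ang)
            py, px = -dx, dy           # perpendicular
            tip_y, tip_x = cy + arm_len * dy, cx + arm_len * dx
            verts_y = [cy + arm_w * py, cy - arm_w * py, tip_y]
            verts_x = [cx + arm_w * px, cx - arm_w * px, tip_x]
            rr, cc = draw_polygon(verts_y, verts_x, shape=canvas.shape)
            mask[rr, cc] = True
    else:
        raise ValueError(f"unknown class {cls!r}")
    canvas[mask] = 1.0
    return mask


def _object_radius(cls: str, area: float) -> float:
    """Bounding radius used for overlap-free placement."""
    if cls == "Spindle":
        return np.sqrt(_SPINDLE_RATIO[1] * area / np.pi)
    if cls == "Spread":
        return 2.3 * np.sqrt(0.8 * area / np.pi)
    return np.sqrt(_ROUND_RATIO[1] * area / np.pi)


def simulate_acinus_timelapse(config: ScreenSimConfig) -> GroundTruthPlate:
    """Render the full time-lapse plate with per-frame ground truth.

    Each object follows a first-order Markov chain over the three classes
    using its condition's (replicate-jittered) transition matrix; area
    grows by ``growth_rate`` per frame; reporter-negative objects appear
    only in the phase-proxy channel.
    """
    rng = np.random.default_rng(config.seed)
    frames: dict[tuple[str, int, int, int], np.ndarray] = {}
    records = []
    size = config.image_size
    classes = np.array(CLASS_NAMES)
    start = np.asarray(config.initial_state_distribution)
    object_id = 0
    for condition in config.condition_names:
        base_matrix = config.matrix_for(condition)
        for replicate in range(1, config.n_replicates + 1):
            matrix = _jitter_matrix(base_matrix, config.replicate_jitter, rng)
            for well in range(1, config.wells_per_condition + 1):
                for fld in range(1, config.fields_per_well + 1):
                    field_name = f"{condition}-r{replicate}-w{well}-f{fld}"
                    stack = np.zeros(
                        (config.n_frames, 2, size, size), dtype=np.float32
                    )
                    # state trajectories and growth
                    n_obj = config.objects_per_field
                    states = sample_state_trajectories(
                        matrix, start, n_obj, config.n_frames, rng
                    )
                    areas = config.initial_area * (
                        (1 + config.growth_rate) ** np.arange(config.n_frames)
                    )
                    reporter = rng.random(n_obj) < config.reporter_positive_fraction
                    # overlap-free placement by rejection sampling
                    max_r = max(
                        _object_radius(classes[s], areas[-1])
                        for s in np.unique(states)
                    )
                    centers = []
                    for _ in range(n_obj):
                        for _attempt in range(500):
                            cy = rng.uniform(max_r + 2, size - max_r - 2)
                            cx = rng.uniform(max_r + 2, size - max_r - 2)
                            if all((cy - oy) ** 2 + (cx - ox) ** 2
                                   > (2 * max_r) ** 2 for oy, ox in centers):
                                centers.append((cy, cx))
                                break
                        else:
                            raise PlacementError(
                                f"cannot place {n_obj} objects in field "
                                f"{field_name} without overlap"
                            )
                    centers = np.array(centers)
                    drift = rng.normal(
                        0, config.step_sd, size=(config.n_frames, n_obj, 2)
                    )
                    drift[0] = 0.0
                    paths = centers[None, :, :] + drift.cumsum(axis=0)
                    paths = np.clip(paths, max_r + 2, size - max_r - 2)
                    orientations = rng.uniform(0, np.pi, size=n_obj)
                    ids = np.arange(object_id, object_id + n_obj)
                    object_id += n_obj
                    for t in range(config.n_frames):
                        phase = stack[t, 0]
                        for i in range(n_obj):
                            cls = classes[states[i, t]]
                            mask = render_acinus(
                                cls, areas[t], orientations[i], phase,
                                center=tuple(paths[t, i]), rng=rng,
                            )
                            if reporter[i]:
                                stack[t, 1][mask] = 1.0
                            records.append(
                                (ids[i], t, float(t), condition, replicate,
                                 well, fld, cls, paths[t, i, 1], paths[t, i, 0],
                                 int(mask.sum()), bool(reporter[i]))
                            )
                        if config.noise_sd > 0:
                            stack[t] += rng.normal(
                                0, config.noise_sd, size=stack[t].shape
                            ).astype(np.float32)
                    frames[(condition, replicate, well, fld)] = stack
    truth = pd.DataFrame.from_records(
        records,
        columns=["object_id", "frame", "time_h", "condition", "replicate",
                 "well", "field", "true_class", "x", "y", "true_area",
                 "reporter_positive"],
    )
    return GroundTruthPlate(frames=frames, truth_table=truth, config=config)


def simulate_screen_counts(
    config: ScreenSimConfig, bin_width_h: float = 12.0
) -> pd.DataFrame:
    """Fast path: phenotype count table without rendering.

    Multinomial draws per condition x replicate x 12-h time bin from the
    Markov-chain occupancy probabilities (replicate-jittered matrices).
    Object-frames are the counting unit, so each object contributes one
    draw per frame; totals equal objects x fields x wells x frames-in-bin.
    Returns the ``condition, replicate, time_bin, class, count, bin_total``
    table consumed by :mod:`acinoscreen.screen_stats`.
    """
    rng = np.random.default_rng(config.seed)
    start = np.asarray(config.initial_state_distribution)
    n_objects = (
        config.objects_per_field
        * config.fields_per_well
        * config.wells_per_condition
    )
    bin_edges = np.arange(0, config.n_frames, int(bin_width_h))
    records = []
    for condition in config.condition_names:
        base_matrix = config.matrix_for(condition)
        for replicate in range(1, config.n_replicates + 1):
            matrix = _jitter_matrix(base_matrix, config.replicate_jitter, rng)
            occ = markov_occupancy(matrix, start, config.n_frames)
            for b, lo in enumerate(bin_edges):
                hi = min(lo + int(bin_width_h), config.n_frames)
                frames_in_bin = hi - lo
                total = n_objects * frames_in_bin
                p = occ[lo:hi].mean(axis=0)
                if total == 0:
                    counts = np.zeros(3, dtype=int)
                else:
                    counts = rng.multinomial(total, p)
                for cls, cnt in zip(CLASS_NAMES, counts):
                    records.append(
                        (condition, replicate, b, cls, int(cnt), int(total))
                    )
    return pd.DataFrame.from_records(
        records,
        columns=["condition", "replicate", "time_bin", "class", "count",
                 "bin_total"],
    )


# ---------------------------------------------------------------------------
# wound assay


@dataclass
class WoundSimConfig:
    n_wells: int = 6
    n_control_wells: int = 3
    n_frames: int = 49
    frame_interval: float = 1.0                 # hours
    closure_halftime_per_well: float | list[float] = 24.0
    closure_steepness: float = 0.3              # logistic slope (1/h)
    mode: str = "sheet"                         # single-cell | sheet | chain
    noise_sd: float = 0.0
    image_size: tuple[int, int] = (120, 160)
    wound_fraction: float = 0.4                 # width of the central band
    plateau: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"single-cell", "sheet", "chain"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_control_wells < 1 or self.n_control_wells > self.n_wells:
            raise ValueError("need 1 <= n_control_wells <= n_wells")
        ht = self.halftimes
        if (ht <= 0).any():
            raise ValueError("halftimes must be positive")

    @property
    def halftimes(self) -> np.ndarray:
        ht = np.asarray(self.closure_halftime_per_well, dtype=float)
        if ht.ndim == 0:
            ht = np.full(self.n_wells, float(ht))
        if ht.shape != (self.n_wells,):
            raise ValueError("one halftime per well required")
        return ht


def _logistic(t: np.ndarray, half: float, steepness: float,
              plateau: float) -> np.ndarray:
    if np.isinf(steepness):
        return np.where(t >= half, plateau, 0.0)
    return plateau / (1.0 + np.exp(-steepness * (t - half)))


def simulate_wound_assay(config: WoundSimConfig) -> list[WoundSeries]:
    """Binary confluence masks for each well with logistic wound closure.

    Frame 0 has a vertical cell-free band (the wound).  Wound-band
    occupancy follows a logistic curve with the well's halftime; the mode
    shapes the advancing front: ``sheet`` a smooth front, ``chain``
    finger-like protrusions, ``single-cell`` scattered pixels ahead of a
    shallow front.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    wound_w = int(round(config.wound_fraction * w))
    lo = (w - wound_w) // 2
    hi = lo + wound_w
    wound_mask = np.zeros((h, w), dtype=bool)
    wound_mask[:, lo:hi] = True
    cell_mask = ~wound_mask
    times = np.arange(config.n_frames) * config.frame_interval
    halftimes = config.halftimes
    series = []
    for well in range(config.n_wells):
        occupancy = _logistic(
            times, halftimes[well], config.closure_steepness, config.plateau
        )
        if config.mode == "chain":
            finger = rng.normal(0, 0.45, size=h)
            # short-range smoothing keeps fingers a few rows wide
            kernel = np.ones(5) / 5
            finger = np.convolve(finger, kernel, mode="same")
        else:
            finger = np.zeros(h)
        masks = np.empty((config.n_frames, h, w), dtype=bool)
        for t in range(config.n_frames):
            frame = cell_mask.copy()
            f = occupancy[t]
            if config.mode == "single-cell":
                # 30% of closure as a shallow front, the rest as scatter
                depth = 0.3 * f * wound_w / 2
                n_scatter = int(0.7 * f * wound_w * h)
                cols = rng.integers(lo, hi, size=n_scatter)
                rows = rng.integers(0, h, size=n_scatter)
                frame[rows, cols] = True
            else:
                depth = f * wound_w / 2
            per_row = np.clip(
                depth * (1 + finger), 0, wound_w / 2
            ).astype(int)
            for r in range(h):
                d = per_row[r] if config.mode != "single-cell" else int(depth)
                if d > 0:
                    frame[r, lo:lo + d] = True
                    frame[r, hi - d:hi] = True
            if config.noise_sd > 0:
                flips = rng.random((h, w)) < config.noise_sd
                frame = frame ^ flips
            masks[t] = frame
        condition = "Scr" if well < config.n_control_wells else "treated"
        series.append(
            WoundSeries(
                masks=masks, wound_mask=wound_mask.copy(),
                cell_mask=cell_mask.copy(), times=times.copy(),
                condition=condition, replicate=1, well=f"W{well + 1}",
            )
        )
    return series


# ---------------------------------------------------------------------------
# puncta


@dataclass
class PunctaSimConfig:
    n_cells: int = 9
    nucleus_radius: int = 12
    cell_radius: int = 40
    puncta_per_channel: int = 20
    puncta_radius: int = 2
    planned_overlap_fraction: float = 0.4
    punctum_intensity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius >= self.cell_radius:
            raise ValueError("nucleus must fit inside the cell")
        if not 0 <= self.planned_overlap_fraction <= 1:
            raise ValueError("planned_overlap_fraction must be in [0, 1]")


@dataclass
class PunctaField:
    """One simulated multi-cell field with ground truth.

    ``nucleus_image`` / ``cell_image`` are the Hoechst and whole-cell-stain
    proxies; ``channel_a`` / ``channel_b`` hold the two puncta stains.
    ``truth`` records punctum centers, radii, channel and pairing.
    """

    nucleus_image: np.ndarray
    cell_image: np.ndarray
    channel_a: np.ndarray
    channel_b: np.ndarray
    cell_centers: list[tuple[int, int]]
    truth: pd.DataFrame
    config: PunctaSimConfig


def simulate_puncta_field(config: PunctaSimConfig) -> PunctaField:
    """Cells on a grid, each with a nucleus and two puncta channels.

    For each channel-A punctum a co-centered channel-B punctum is planted
    with probability ``planned_overlap_fraction``; all other puncta keep a
    minimum center separation of a little over two punctum diameters so
    unplanned overlap cannot occur even after detection.  The realized overlap fraction is therefore
    binomial around the planned value.
    """
    rng = np.random.default_rng(config.seed)
    n_side = int(np.ceil(np.sqrt(config.n_cells)))
    pitch = 2 * config.cell_radius + 8
    size = n_side * pitch + 8
    nucleus_image = np.zeros((size, size), dtype=np.float32)
    cell_image = np.zeros_like(nucleus_image)
    channel_a = np.zeros_like(nucleus_image)
    channel_b = np.zeros_like(nucleus_image)
    centers = []
    records = []
    # separation leaves slack for detection masks a pixel wider than planted
    min_sep = 2 * config.puncta_radius + 5
    max_r = config.cell_radius - config.puncta_radius - 2
    for i in range(config.n_cells):
        gy, gx = divmod(i, n_side)
        cy = 4 + config.cell_radius + gy * pitch
        cx = 4 + config.cell_radius + gx * pitch
        centers.append((cy, cx))
        rr, cc = draw_disk((cy, cx), config.cell_radius,
                           shape=cell_image.shape)
        cell_image[rr, cc] = 1.0
        rr, cc = draw_disk((cy, cx), config.nucleus_radius,
                           shape=nucleus_image.shape)
        nucleus_image[rr, cc] = 1.0

        placed: list[tuple[float, float]] = []

        def place_one() -> tuple[float, float]:
            for _ in range(2000):
                r = max_r * np.sqrt(rng.random())
                theta = rng.uniform(0, 2 * np.pi)
                py, px = cy + r * np.sin(theta), cx + r * np.cos(theta)
                if all((py - qy) ** 2 + (px - qx) ** 2 >= min_sep ** 2
                       for qy, qx in placed):
                    placed.append((py, px))
                    return py, px
            raise PlacementError(
                f"cannot place punctum inside cell {i} without overlap"
            )

        paired = rng.random(config.puncta_per_channel) \
            < config.planned_overlap_fraction
        n_b_unpaired = config.puncta_per_channel - int(paired.sum())
        for j in range(config.puncta_per_channel):
            py, px = place_one()
            rr, cc = draw_disk((py, px), config.puncta_radius,
                               shape=channel_a.shape)
            channel_a[rr, cc] = config.punctum_intensity
            if paired[j]:
                channel_b[rr, cc] = config.punctum_intensity
            records.append((i, "A", py, px, config.puncta_radius,
                            bool(paired[j])))
            if paired[j]:
                records.append((i, "B", py, px, config.puncta_radius, True))
        for _ in range(n_b_unpaired):
            py, px = place_one()
            rr, cc = draw_disk((py, px), config.puncta_radius,
                               shape=channel_b.shape)
            channel_b[rr, cc] = config.punctum_intensity
            records.append((i, "B", py, px, config.puncta_radius, False))
    truth = pd.DataFrame.from_records(
        records, columns=["cell", "channel", "y", "x", "radius", "paired"]
    )
    return PunctaField(
        nucleus_image=nucleus_image, cell_image=cell_image,
        channel_a=channel_a, channel_b=channel_b,
        cell_centers=centers, truth=truth, config=config,
    )


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortSimConfig:
    group_sizes: tuple[int, ...] = (12, 12, 9)
    incidence_probability_per_group: tuple[float, ...] = (0.75, 1.0, 0.67)
    count_distribution_per_group: tuple[float, ...] = (2.0, 4.0, 1.0)
    group_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(self.incidence_probability_per_group):
            raise ValueError("one incidence probability per group required")
        if len(self.group_sizes) != len(self.count_distribution_per_group):
            raise ValueError("one count parameter per group required")
        if any(n < 1 for n in self.group_sizes):
            raise ValueError("group sizes must be >= 1")
        if any(not 0 <= p <= 1
               for p in self.incidence_probability_per_group):
            raise ValueError("incidence probabilities must be in [0, 1]")
        if self.group_names is None:
            self.group_names = tuple(
                f"group{i + 1}" for i in range(len(self.group_sizes))
            )


def simulate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Per-animal incidence flags and metastasis counts.

    ``has_metastasis`` is Bernoulli per group; conditional on a positive
    flag the count is ``1 + Poisson(lambda_group)``, otherwise 0.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    for name, n, p, lam in zip(
        config.group_names, config.group_sizes,
        config.incidence_probability_per_group,
        config.count_distribution_per_group,
    ):
        flags = rng.random(n) < p
        counts = np.where(flags, 1 + rng.poisson(lam, size=n), 0)
        for flag, count in zip(flags, counts):
            records.append((name, bool(flag), int(count)))
    return pd.DataFrame.from_records(
        records, columns=["group", "has_metastasis", "metastasis_count"]
    )


# ---------------------------------------------------------------------------
# feature-space generator used for classifier benchmarking


def make_gaussian_classes(
    n_per_class: int = 500,
    n_features: int = 8,
    separation: float = 2.0,
    class_names: tuple[str, ...] = CLASS_NAMES,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Spherical Gaussian classes with means ``separation`` SD apart.

    Class means sit at vertices of a balanced sign code (Hadamard rows
    scaled to ``separation / 2``): every pair of class means differs by
    ``separation`` standard deviations along each of the features that
    distinguish that pair (half of them), with unit SD throughout.
    Returns ``(features, labels)`` with feature columns
    ``f0..f{n_features-1}``.
    """
    if n_features < 4:
        raise ValueError("need at least four features for the sign code")
    rng = np.random.default_rng(seed)
    codes = np.array(
        [[1, 1, 1, 1], [1, -1, 1, -1], [1, 1, -1, -1], [1, -1, -1, 1]]
    )
    if len(class_names) > codes.shape[0]:
        raise ValueError("at most four classes supported")
    reps = int(np.ceil(n_features / 4))
    blocks = []
    labels = []
    for k, name in enumerate(class_names):
        mean = np.tile(codes[k], reps)[:n_features] * (separation / 2.0)
        blocks.append(rng.normal(mean, 1.0, size=(n_per_class, n_features)))
        labels.extend([name] * n_per_class)
    x = np.vstack(blocks)
    features = pd.DataFrame(x, columns=[f"f{i}" for i in range(n_features)])
    return features, np.asarray(labels)
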