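"""Synthetic BOLD experiments with planted memory representations.

This module generates complete two-session recall experiments on a
digital phantom: disjoint region-of-interest (ROI) masks on a regular
voxel grid, a sparse multivoxel weight map per individual memory, a
pseudo-random trial schedule with vividness/consistency ratings, and a
4D BOLD series built by a forward model — recall-period boxcars scaled
by each memory's weight map, convolved with the canonical haemodynamic
response function, plus linear scanner drift and Gaussian noise.

Because the planted maps are known exactly, every downstream stage
(preprocessing, searchlight feature selection, ECOC-SVM decoding,
information-map overlap, group statistics) can be tested against ground
truth without access to scanner data.

The emulated design: nine memories in three conditions (three memories
each), every memory recalled 14 times for 12 s after a 3 s word cue,
126 trials split into two sessions of 63, no memory repeated on
consecutive trials, TR 3.5 s, 1.5 mm isotropic voxels.  A "study" is one
full pass through this design; two studies share one ground truth whose
per-memory supports can be made to coincide or diverge across studies
(``timepoint_overlap``) and across conditions (``support_overlap``).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from nilearn.glm.first_level import spm_hrf

from .core import VolumeSeries, derive_seed, save_mask_nifti, write_events_tsv


class CapacityError(ValueError):
    """The requested ROIs cannot be placed disjointly on the grid."""


class SchedulingError(RuntimeError):
    """No valid no-immediate-repeat trial order was found."""


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Timing and counts of the recall experiment.

    Durations are seconds.  ``rating_s`` covers both the vividness and
    the consistency rating (up to 3 s each).  ``retention_prob`` is the
    probability that a trial passes the vividness>=4 & consistency>=4
    filter; the default reproduces the observed average of ~11 retained
    trials out of 14 per memory.
    """

    n_memories_per_condition: int = 3
    conditions: tuple[str, ...] = ("recent", "remote", "control")
    repetitions: int = 14
    n_sessions: int = 2
    cue_s: float = 3.0
    recall_s: float = 12.0
    tone_s: float = 1.5
    rating_s: float = 6.0
    rest_s: float = 4.0
    tr_s: float = 3.5
    retention_prob: float = 0.79
    post_rest_s: float = 14.0

    def __post_init__(self) -> None:
        for name in ("cue_s", "recall_s", "tone_s", "rating_s", "rest_s", "tr_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.retention_prob <= 1.0:
            raise ValueError("retention_prob must be in [0, 1]")
        if (self.repetitions * self.n_memories) % self.n_sessions != 0:
            raise ValueError(
                "repetitions x total memories must be divisible by n_sessions"
            )

    @property
    def n_memories(self) -> int:
        return self.n_memories_per_condition * len(self.conditions)

    @property
    def memory_labels(self) -> list[str]:
        return [
            f"{cond}-m{i + 1}"
            for cond in self.conditions
            for i in range(self.n_memories_per_condition)
        ]

    def condition_of(self, memory_label: str) -> str:
        return memory_label.rsplit("-m", 1)[0]

    @property
    def n_trials(self) -> int:
        return self.repetitions * self.n_memories

    @property
    def trials_per_session(self) -> int:
        return self.n_trials // self.n_sessions

    @property
    def trial_length_s(self) -> float:
        return self.cue_s + self.recall_s + self.tone_s + self.rating_s + self.rest_s

    @property
    def session_volumes(self) -> int:
        dur = self.trials_per_session * self.trial_length_s + self.post_rest_s
        return int(math.ceil(dur / self.tr_s))


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

@dataclass
class PhantomGeometry:
    """Voxel grid plus named, pairwise-disjoint binary ROI masks.

    ``long_axis`` is the grid axis along which elongated (hippocampus-
    like) masks extend, standing in for the anatomical anterior-posterior
    direction.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    roi_masks: dict[str, np.ndarray]
    long_axis: int = 2

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        occupancy = np.zeros(self.grid_shape, dtype=int)
        for name, mask in self.roi_masks.items():
            if mask.shape != tuple(self.grid_shape):
                raise ValueError(f"mask {name!r} does not match the grid shape")
            if not mask.any():
                raise ValueError(f"mask {name!r} is empty")
            occupancy += mask.astype(int)
        if (occupancy > 1).any():
            raise ValueError("ROI masks overlap")

    def roi_size(self, name: str) -> int:
        return int(self.roi_masks[name].sum())

    def roi_voxel_index(self, name: str) -> np.ndarray:
        """(n_vox, 3) voxel coordinates in C-scan order (matches data[mask])."""
        return np.argwhere(self.roi_masks[name])


def _ellipsoid_mask(
    n_target: int,
    elongation: float,
    long_axis: int,
    center_jitter: np.ndarray,
) -> np.ndarray:
    """Boolean box holding exactly ``n_target`` voxels of an axis-aligned
    ellipsoid elongated by ``elongation`` along ``long_axis``."""
    c0 = (3.0 * n_target / (4.0 * math.pi * elongation)) ** (1.0 / 3.0)
    semi = np.array([c0, c0, c0])
    semi[long_axis] *= elongation
    # generous candidate box, then keep the n_target elliptically closest
    half = np.ceil(semi * 1.6).astype(int) + 1
    shape = 2 * half + 1
    grids = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
    center = center_jitter  # fractional offset in (-0.5, 0.5)
    d2 = sum(
        ((g - center[a]) / semi[a]) ** 2 for a, g in enumerate(grids)
    )
    flat = d2.ravel()
    if n_target > flat.size:
        raise CapacityError("ROI target larger than candidate box")
    order = np.argsort(flat, kind="stable")[:n_target]
    mask = np.zeros(flat.size, dtype=bool)
    mask[order] = True
    return mask.reshape(tuple(shape))


def build_phantom_rois(
    grid_shape: tuple[int, int, int],
    roi_size_targets: dict[str, int],
    seed: int,
    voxel_size_mm: float = 1.5,
    long_axis: int = 2,
    elongation: dict[str, float] | None = None,
) -> PhantomGeometry:
    """Place disjoint ellipsoidal ROI masks of the requested voxel counts.

    Masks named with a hippocampal prefix (``HC``/``hippo``) are by
    default elongated 3:1 along ``long_axis`` so that the long-axis
    split is meaningful; other masks are spherical.  Voxel counts are
    exact.  Raises :class:`CapacityError` when the grid cannot host the
    ROIs disjointly.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if any(t <= 0 for t in roi_size_targets.values()):
        raise ValueError("roi size targets must be positive")
    if sum(roi_size_targets.values()) > np.prod(grid_shape):
        raise CapacityError("total ROI volume exceeds the grid")
    rng = derive_seed(seed, "phantom")
    stack_axis = 0 if long_axis != 0 else 1
    masks: dict[str, np.ndarray] = {}
    cursor = 0
    for name, target in roi_size_targets.items():
        elong = 1.0
        if elongation and name in elongation:
            elong = elongation[name]
        elif name.lower().startswith(("hc", "hippo")):
            elong = 3.0
        jitter = rng.uniform(-0.4, 0.4, size=3)
        box = _ellipsoid_mask(int(target), elong, long_axis, jitter)
        # trim empty planes so the bounding box is tight
        occupied = np.argwhere(box)
        lo, hi = occupied.min(axis=0), occupied.max(axis=0) + 1
        box = box[tuple(slice(a, b) for a, b in zip(lo, hi))]
        for axis, extent in enumerate(box.shape):
            limit = grid_shape[axis]
            if axis == stack_axis:
                continue
            if extent > limit:
                raise CapacityError(
                    f"ROI {name!r} extent {extent} exceeds grid axis {axis}"
                )
        if cursor + box.shape[stack_axis] + 1 > grid_shape[stack_axis]:
            raise CapacityError("grid too small to place all ROIs disjointly")
        full = np.zeros(grid_shape, dtype=bool)
        sl = [slice(0, e) for e in box.shape]
        sl[stack_axis] = slice(cursor, cursor + box.shape[stack_axis])
        # centre on the non-stacking axes
        for axis in range(3):
            if axis == stack_axis:
                continue
            offset = (grid_shape[axis] - box.shape[axis]) // 2
            sl[axis] = slice(offset, offset + box.shape[axis])
        full[tuple(sl)] = box
        masks[name] = full
        cursor += box.shape[stack_axis] + 1
    return PhantomGeometry(
        grid_shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        roi_masks=masks,
        long_axis=long_axis,
    )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted multivoxel representations for every (ROI, study, memory).

    ``pattern_maps[roi][study][memory]`` is a dense weight vector over
    the ROI's voxels (C-scan order), zero off the memory's support.
    ``amplitudes[(roi, condition)]`` scales the signal; setting it to 0
    removes all memory information from that ROI/condition.
    """

    pattern_maps: dict[str, list[dict[str, np.ndarray]]]
    amplitudes: dict[tuple[str, str], float]
    support_overlap: float
    timepoint_overlap: float
    support_fraction: float
    noise_sd: float
    drift_slope: float
    seed: int

    @property
    def n_studies(self) -> int:
        first = next(iter(self.pattern_maps.values()))
        return len(first)

    def support(self, roi: str, study: int, memory: str) -> np.ndarray:
        return np.flatnonzero(self.pattern_maps[roi][study][memory])

    # -- lossless JSON round trip ---------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "pattern_maps": {
                roi: [
                    {m: w.tolist() for m, w in study_maps.items()}
                    for study_maps in studies
                ]
                for roi, studies in self.pattern_maps.items()
            },
            "amplitudes": {f"{r}\t{c}": a for (r, c), a in self.amplitudes.items()},
            "support_overlap": self.support_overlap,
            "timepoint_overlap": self.timepoint_overlap,
            "support_fraction": self.support_fraction,
            "noise_sd": self.noise_sd,
            "drift_slope": self.drift_slope,
            "seed": self.seed,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GroundTruth":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        return cls(
            pattern_maps={
                roi: [
                    {m: np.asarray(w, dtype=np.float64) for m, w in study_maps.items()}
                    for study_maps in studies
                ]
                for roi, studies in payload["pattern_maps"].items()
            },
            amplitudes={
                tuple(k.split("\t")): v for k, v in payload["amplitudes"].items()
            },
            support_overlap=payload["support_overlap"],
            timepoint_overlap=payload["timepoint_overlap"],
            support_fraction=payload["support_fraction"],
            noise_sd=payload["noise_sd"],
            drift_slope=payload["drift_slope"],
            seed=payload["seed"],
        )


def _blob_near(
    coords: np.ndarray, pool: np.ndarray, size: int, center: np.ndarray
) -> np.ndarray:
    """The ``size`` pool voxels nearest (Euclidean) to ``center`` — a
    spatially compact blob, mimicking a locally clustered neural
    population (spatial clustering is what makes searchlight
    information maps separable)."""
    d2 = np.sum((coords[pool] - center) ** 2, axis=1)
    order = np.argsort(d2, kind="stable")[:size]
    return pool[order]


def _condition_supports(
    rng: np.random.Generator,
    coords: np.ndarray,
    n_vox: int,
    n_mem: int,
    size: int,
    overlap: float,
    base_supports: list[np.ndarray] | None,
    base_center: np.ndarray | None,
    jitter: float = 1.5,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Supports for one condition's memories as blobs around a shared
    condition centre.

    With no base (the reference condition) the centre is a random ROI
    voxel.  A constrained condition shares ``round(overlap * size)``
    voxels with each base memory's support; its fresh voxels avoid the
    base condition's union and cluster around the available voxel
    farthest from the base centre — modelling a spatially segregated
    (e.g. anterior vs posterior) population when overlap is low.
    """
    all_idx = np.arange(n_vox)
    if base_supports is None:
        # the reference condition occupies a pole of the ROI (a voxel in
        # the farthest quintile from the centroid), so that a condition
        # constrained to avoid it can settle at the opposite pole — the
        # along-the-long-axis segregation the overlap analyses probe
        d_centroid = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
        cutoff = np.quantile(d_centroid, 0.8)
        extremes = np.flatnonzero(d_centroid >= cutoff)
        center = coords[int(rng.choice(extremes))]
        supports = []
        for _ in range(n_mem):
            jittered = center + rng.normal(0.0, jitter, size=coords.shape[1])
            supports.append(np.sort(_blob_near(coords, all_idx, size, jittered)))
        return supports, center

    k = int(round(overlap * size))
    n_fresh = size - k
    base_union = np.unique(np.concatenate(base_supports))
    pool = np.setdiff1d(all_idx, base_union)
    supports = []
    if n_fresh == 0:
        for base in base_supports:
            supports.append(np.sort(rng.choice(base, size=size, replace=False)))
        return supports, base_center.copy()
    if len(pool) >= n_fresh:
        d2 = np.sum((coords[pool] - base_center) ** 2, axis=1)
        center = coords[pool[int(np.argmax(d2))]]
        per_memory_pool = [pool] * n_mem
    else:
        # not enough untouched voxels: only avoid each memory's own base
        center = coords[int(rng.integers(n_vox))]
        per_memory_pool = [np.setdiff1d(all_idx, b) for b in base_supports]
    for base, mem_pool in zip(base_supports, per_memory_pool):
        if n_fresh > len(mem_pool):
            raise CapacityError(
                "ROI too small for the requested support size and overlap"
            )
        shared = rng.choice(base, size=k, replace=False) if k else np.empty(0, int)
        jittered = center + rng.normal(0.0, jitter, size=coords.shape[1])
        fresh = _blob_near(coords, mem_pool, n_fresh, jittered)
        supports.append(np.sort(np.concatenate([shared, fresh])))
    return supports, center


def plant_patterns(
    geometry: PhantomGeometry,
    design: DesignSpec,
    amplitudes: dict[tuple[str, str], float] | float = 1.0,
    support_overlap: float = 1.0,
    seed: int = 0,
    support_fraction: float | dict[str, float] = 0.4,
    timepoint_overlap: float = 1.0,
    noise_sd: float = 1.0,
    drift_slope: float = 0.05,
    n_studies: int = 2,
) -> GroundTruth:
    """Plant one sparse standard-normal weight map per (ROI, study, memory).

    Each memory's support covers ``support_fraction`` of its ROI (a
    scalar, or a per-ROI-name mapping).
    ``support_overlap`` fixes the fraction of support voxels a memory
    shares with the same-index memory of the *first* condition (1 =
    identical supports, 0 = supports drawn from voxels untouched by the
    first condition).  ``timepoint_overlap`` plays the same role between
    study 1 and study 2 for the same memory (0 = the representation
    relocates entirely between studies).
    """
    fraction_by_roi = (
        dict(support_fraction)
        if isinstance(support_fraction, dict)
        else {roi: support_fraction for roi in geometry.roi_masks}
    )
    for name, value in (
        ("support_overlap", support_overlap),
        ("timepoint_overlap", timepoint_overlap),
        *[("support_fraction", v) for v in fraction_by_roi.values()],
    ):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rois = list(geometry.roi_masks)
    if isinstance(amplitudes, (int, float)):
        amplitudes = {
            (roi, cond): float(amplitudes)
            for roi in rois
            for cond in design.conditions
        }
    for (roi, cond), amp in amplitudes.items():
        if amp < 0:
            raise ValueError(f"amplitude for {(roi, cond)} must be >= 0")
    for roi in rois:
        for cond in design.conditions:
            amplitudes.setdefault((roi, cond), 1.0)

    pattern_maps: dict[str, list[dict[str, np.ndarray]]] = {}
    for roi in rois:
        n_vox = geometry.roi_size(roi)
        coords = geometry.roi_voxel_index(roi).astype(float)
        s = max(1, int(round(fraction_by_roi.get(roi, 0.4) * n_vox)))
        rng = derive_seed(seed, "patterns", roi)
        n_mem = design.n_memories_per_condition
        studies: list[dict[str, np.ndarray]] = []
        study1_supports: dict[str, list[np.ndarray]] = {}
        study1_centers: dict[str, np.ndarray] = {}
        for study in range(n_studies):
            maps: dict[str, np.ndarray] = {}
            ref_cond = design.conditions[0]
            for cond in design.conditions:
                if study == 0 and cond == ref_cond:
                    supports, center = _condition_supports(
                        rng, coords, n_vox, n_mem, s, 0.0, None, None
                    )
                elif study == 0:
                    supports, center = _condition_supports(
                        rng,
                        coords,
                        n_vox,
                        n_mem,
                        s,
                        support_overlap,
                        study1_supports[ref_cond],
                        study1_centers[ref_cond],
                    )
                else:
                    supports, center = _condition_supports(
                        rng,
                        coords,
                        n_vox,
                        n_mem,
                        s,
                        timepoint_overlap,
                        study1_supports[cond],
                        study1_centers[cond],
                    )
                if study == 0:
                    study1_supports[cond] = supports
                    study1_centers[cond] = center
                for i, support in enumerate(supports):
                    weights = np.zeros(n_vox)
                    weights[support] = rng.standard_normal(len(support))
                    maps[f"{cond}-m{i + 1}"] = weights
            studies.append(maps)
        pattern_maps[roi] = studies

    return GroundTruth(
        pattern_maps=pattern_maps,
        amplitudes=amplitudes,
        support_overlap=support_overlap,
        timepoint_overlap=timepoint_overlap,
        support_fraction=support_fraction,
        noise_sd=noise_sd,
        drift_slope=drift_slope,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# trial schedule
# ---------------------------------------------------------------------------

def _order_without_repeats(
    tokens: list[str], rng: np.random.Generator, max_tries: int = 50
) -> list[str]:
    """Uniform-ish random order of ``tokens`` with no two equal neighbours.

    Shuffles, then repairs remaining adjacent duplicates by swapping one
    member of a violating pair to a randomly chosen compatible position;
    infeasible requests (one label on more than every other trial) fail
    immediately."""
    tokens = list(tokens)
    n = len(tokens)
    counts: dict[str, int] = {}
    for t in tokens:
        counts[t] = counts.get(t, 0) + 1
    if max(counts.values()) > (n + 1) // 2:
        raise SchedulingError(
            "no trial order without immediate repeats exists for these counts"
        )
    for _ in range(max_tries):
        rng.shuffle(tokens)
        for _ in range(10 * n):
            viols = [i for i in range(1, n) if tokens[i] == tokens[i - 1]]
            if not viols:
                return tokens
            i = viols[0]
            candidates = [
                j
                for j in range(n)
                if abs(j - i) > 1
                and tokens[j] != tokens[i]
                and (j == 0 or tokens[j - 1] != tokens[i])
                and (j == n - 1 or tokens[j + 1] != tokens[i])
                and tokens[j] != tokens[i - 1]
                and (i == n - 1 or tokens[j] != tokens[i + 1])
            ]
            if not candidates:
                break
            j = int(rng.choice(candidates))
            tokens[i], tokens[j] = tokens[j], tokens[i]
    raise SchedulingError(
        "no trial order without immediate repeats found; check memory counts"
    )


def _rating_distribution(retention_prob: float) -> np.ndarray:
    """Marginal over ratings 1..5 such that two independent draws are
    both >= 4 with probability ``retention_prob``."""
    q = math.sqrt(retention_prob)
    p_high = q / 2.0
    p_low = (1.0 - q) / 3.0
    return np.array([p_low, p_low, p_low, p_high, p_high])


def make_trial_schedule(design: DesignSpec, seed: int) -> pd.DataFrame:
    """Pseudo-random trial table for one study.

    Every memory appears exactly ``design.repetitions`` times, sessions
    are equal-sized, no memory occurs on consecutive trials within a
    session, and onsets (start of the 12 s recall period, seconds from
    the start of the concatenated series) follow the cue/recall/tone/
    rating/rest timing grid.  Vividness and consistency ratings are
    drawn so that the expected fraction of trials passing the >=4/>=4
    filter equals ``design.retention_prob``.
    """
    if design.n_memories < 2:
        raise SchedulingError("at least two distinct memories are required")
    rng = derive_seed(seed, "schedule")
    labels = design.memory_labels
    n_sess = design.n_sessions
    base, extra = divmod(design.repetitions, n_sess)
    per_session_counts = [dict.fromkeys(labels, base) for _ in range(n_sess)]
    if extra:
        capacity = [design.trials_per_session - base * len(labels)] * n_sess
        for label in labels:
            open_sessions = [s for s in range(n_sess) if capacity[s] > 0]
            chosen = rng.choice(
                open_sessions, size=extra, replace=False
            )
            for s in chosen:
                per_session_counts[s][label] += 1
                capacity[s] -= 1

    probs = _rating_distribution(design.retention_prob)
    rows = []
    session_vols = design.session_volumes
    for s in range(n_sess):
        tokens = [
            label
            for label, count in per_session_counts[s].items()
            for _ in range(count)
        ]
        ordered = _order_without_repeats(tokens, rng)
        session_start = s * session_vols * design.tr_s
        for i, label in enumerate(ordered):
            onset = session_start + i * design.trial_length_s + design.cue_s
            rows.append(
                {
                    "onset": onset,
                    "duration": design.recall_s,
                    "memory": label,
                    "condition": design.condition_of(label),
                    "session": s,
                    "vividness": int(rng.choice(5, p=probs)) + 1,
                    "consistency": int(rng.choice(5, p=probs)) + 1,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BOLD forward model
# ---------------------------------------------------------------------------

def _convolved_regressors(
    schedule: pd.DataFrame, design: DesignSpec, n_volumes: int
) -> tuple[list[str], np.ndarray]:
    """HRF-convolved recall-period regressor per memory, sampled at TR.

    Returns (memory labels, array of shape (n_volumes, n_memories)).
    """
    dt = 0.1
    steps_per_tr = int(round(design.tr_s / dt))
    n_fine = n_volumes * steps_per_tr + 1
    kernel = spm_hrf(design.tr_s, oversampling=steps_per_tr)
    labels = design.memory_labels
    neural = np.zeros((n_fine, len(labels)))
    label_col = {m: j for j, m in enumerate(labels)}
    for _, trial in schedule.iterrows():
        j = label_col[trial["memory"]]
        a = int(round(trial["onset"] / dt))
        b = int(round((trial["onset"] + trial["duration"]) / dt))
        if b > n_fine:
            raise ValueError(
                f"trial at onset {trial['onset']}s exceeds the run length"
            )
        neural[a:b, j] = 1.0
    fine = np.empty_like(neural)
    for j in range(neural.shape[1]):
        fine[:, j] = np.convolve(neural[:, j], kernel)[:n_fine]
    vol_idx = np.arange(n_volumes) * steps_per_tr
    return labels, fine[vol_idx]


def synthesize_bold(
    geometry: PhantomGeometry,
    truth: GroundTruth,
    schedule: pd.DataFrame,
    design: DesignSpec,
    study: int = 0,
) -> VolumeSeries:
    """Forward-model a 4D BOLD series for one study.

    Each ROI voxel's time course is the sum over memories of the
    HRF-convolved recall boxcar times the voxel's planted weight, scaled
    by the (ROI, condition) amplitude; a per-session linear drift and
    i.i.d. Gaussian noise (over the whole grid) are added on top.
    """
    n_sess = int(schedule["session"].max()) + 1
    if n_sess != design.n_sessions:
        raise ValueError("schedule and design disagree on session count")
    session_vols = design.session_volumes
    n_volumes = n_sess * session_vols
    labels, regressors = _convolved_regressors(schedule, design, n_volumes)

    data = np.zeros(geometry.grid_shape + (n_volumes,))
    for roi, mask in geometry.roi_masks.items():
        maps = truth.pattern_maps[roi][study]
        weight_matrix = np.stack([maps[m] for m in labels], axis=0)
        amp = np.array(
            [truth.amplitudes[(roi, design.condition_of(m))] for m in labels]
        )
        # (n_volumes, n_mem) @ (n_mem, n_vox) -> (n_volumes, n_vox)
        signal = (regressors * amp) @ weight_matrix
        data[mask] = signal.T

    if truth.drift_slope:
        within = np.tile(np.arange(session_vols), n_sess)
        data += truth.drift_slope * within
    if truth.noise_sd:
        rng = derive_seed(truth.seed, "noise", f"study{study}")
        data += rng.normal(0.0, truth.noise_sd, size=data.shape)
    bounds = [(s * session_vols, (s + 1) * session_vols) for s in range(n_sess)]
    return VolumeSeries(
        data=data,
        voxel_size_mm=geometry.voxel_size_mm,
        tr_s=design.tr_s,
        session_bounds=bounds,
    )


# ---------------------------------------------------------------------------
# one-call subject simulation and on-disk dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSubject:
    geometry: PhantomGeometry
    truth: GroundTruth
    schedules: list[pd.DataFrame]
    bold: list[VolumeSeries]
    design: DesignSpec


def simulate_subject(
    design: DesignSpec,
    grid_shape: tuple[int, int, int],
    roi_size_targets: dict[str, int],
    seed: int,
    amplitudes: dict[tuple[str, str], float] | float = 1.0,
    support_overlap: float = 1.0,
    timepoint_overlap: float = 1.0,
    support_fraction: float = 0.4,
    noise_sd: float = 1.0,
    drift_slope: float = 0.05,
    n_studies: int = 2,
    voxel_size_mm: float = 1.5,
    elongation: dict[str, float] | None = None,
) -> SimulatedSubject:
    """Generate geometry, ground truth, schedules and BOLD for one subject."""
    geometry = build_phantom_rois(
        grid_shape,
        roi_size_targets,
        seed=seed,
        voxel_size_mm=voxel_size_mm,
        elongation=elongation,
    )
    truth = plant_patterns(
        geometry,
        design,
        amplitudes=amplitudes,
        support_overlap=support_overlap,
        seed=seed,
        support_fraction=support_fraction,
        timepoint_overlap=timepoint_overlap,
        noise_sd=noise_sd,
        drift_slope=drift_slope,
        n_studies=n_studies,
    )
    schedules, bold = [], []
    for study in range(n_studies):
        sched = make_trial_schedule(design, seed=int(seed) * n_studies + study)
        schedules.append(sched)
        bold.append(synthesize_bold(geometry, truth, sched, design, study=study))
    return SimulatedSubject(
        geometry=geometry,
        truth=truth,
        schedules=schedules,
        bold=bold,
        design=design,
    )


def write_dataset(subject: SimulatedSubject, out_dir) -> None:
    """Write BOLD (NIfTI-1 4D), masks (NIfTI-1 3D), events (TSV) and
    ground truth (JSON) for one simulated subject."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for study, (sched, vol) in enumerate(zip(subject.schedules, subject.bold)):
        nib.save(vol.to_nifti(), str(out / f"bold_study{study + 1}.nii.gz"))
        write_events_tsv(sched, out / f"events_study{study + 1}.tsv")
    for name, mask in subject.geometry.roi_masks.items():
        save_mask_nifti(
            mask, subject.geometry.voxel_size_mm, out / f"mask_{name}.nii.gz"
        )
    subject.truth.to_json(out / "ground_truth.json")
    (out / "design.json").write_text(json.dumps(asdict(subject.design), indent=1))
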