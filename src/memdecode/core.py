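"""Core containers shared across the pipeline.

The pipeline operates on three kinds of objects: a 4D BOLD series on a
regular voxel grid (:class:`VolumeSeries`), an ordered table of recall
trials (a plain :class:`pandas.DataFrame` with the columns listed in
:data:`TRIAL_COLUMNS`), and per-trial multivoxel patterns restricted to
one region of interest (:class:`TrialPatternSet`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

#: Required columns of a trial/events table.  ``onset`` is in seconds from
#: the start of the concatenated series, ``duration`` is the recall period
#: in seconds, ``memory`` and ``condition`` are string labels, ``session``
#: is a 0-based integer, ``vividness`` and ``consistency`` are 1-5 ratings.
TRIAL_COLUMNS = (
    "onset",
    "duration",
    "memory",
    "condition",
    "session",
    "vividness",
    "consistency",
)


@dataclass
class VolumeSeries:
    """A 4D scalar field (x, y, z, t) on an isotropic voxel grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, nt)
        BOLD signal in arbitrary units.
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    tr_s : float
        Repetition time (seconds between successive volumes).
    session_bounds : list of (start, stop)
        Half-open volume-index ranges partitioning the time axis into
        scanning sessions.
    """

    data: np.ndarray
    voxel_size_mm: float
    tr_s: float
    session_bounds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not self.session_bounds:
            self.session_bounds = [(0, self.data.shape[3])]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def copy_with(self, data: np.ndarray) -> "VolumeSeries":
        return VolumeSeries(
            data=data,
            voxel_size_mm=self.voxel_size_mm,
            tr_s=self.tr_s,
            session_bounds=list(self.session_bounds),
        )

    # -- NIfTI round trip ------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine)
        img.header.set_zooms((self.voxel_size_mm,) * 3 + (self.tr_s,))
        return img

    @classmethod
    def from_nifti(
        cls, img: nib.Nifti1Image, session_bounds=None
    ) -> "VolumeSeries":
        zooms = img.header.get_zooms()
        return cls(
            data=np.asarray(img.dataobj, dtype=np.float64),
            voxel_size_mm=float(zooms[0]),
            tr_s=float(zooms[3]) if len(zooms) > 3 else 1.0,
            session_bounds=session_bounds or [],
        )


@dataclass
class TrialPatternSet:
    """One feature vector per retained trial over a ROI's voxels.

    ``patterns`` has shape (n_trials, n_roi_voxels); row order follows the
    trial table.  Voxel order is the C-order scan of the ROI mask, so
    ``volume[mask]`` and pattern columns align.
    """

    patterns: np.ndarray
    memory_labels: np.ndarray
    condition_labels: np.ndarray
    roi_name: str
    trial_index: np.ndarray

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=np.float64)
        self.memory_labels = np.asarray(self.memory_labels)
        self.condition_labels = np.asarray(self.condition_labels)
        self.trial_index = np.asarray(self.trial_index)
        n = self.patterns.shape[0]
        if not (len(self.memory_labels) == len(self.condition_labels) == len(self.trial_index) == n):
            raise ValueError("label arrays must match the number of pattern rows")

    @property
    def n_trials(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    def subset_condition(self, condition: str) -> "TrialPatternSet":
        keep = self.condition_labels == condition
        return TrialPatternSet(
            patterns=self.patterns[keep],
            memory_labels=self.memory_labels[keep],
            condition_labels=self.condition_labels[keep],
            roi_name=self.roi_name,
            trial_index=self.trial_index[keep],
        )

    # -- serialisation: matrix file + JSON sidecar -----------------------
    def save(self, prefix) -> None:
        prefix = str(prefix)
        np.savetxt(prefix + ".patterns.tsv", self.patterns, delimiter="\t")
        digest = hashlib.sha256(
            np.ascontiguousarray(self.patterns).tobytes()
        ).hexdigest()
        sidecar = {
            "roi_name": self.roi_name,
            "memory_labels": self.memory_labels.tolist(),
            "condition_labels": self.condition_labels.tolist(),
            "trial_index": self.trial_index.tolist(),
            "sha256": digest,
        }
        with open(prefix + ".patterns.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, prefix) -> "TrialPatternSet":
        prefix = str(prefix)
        patterns = np.atleast_2d(np.loadtxt(prefix + ".patterns.tsv", delimiter="\t"))
        with open(prefix + ".patterns.json") as fh:
            sidecar = json.load(fh)
        return cls(
            patterns=patterns,
            memory_labels=np.asarray(sidecar["memory_labels"]),
            condition_labels=np.asarray(sidecar["condition_labels"]),
            roi_name=sidecar["roi_name"],
            trial_index=np.asarray(sidecar["trial_index"]),
        )


# -- trial table I/O ------------------------------------------------------

def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    return trials


def write_events_tsv(trials: pd.DataFrame, path) -> None:
    validate_trial_table(trials)
    trials.loc[:, list(TRIAL_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    trials = pd.read_csv(path, sep="\t")
    return validate_trial_table(trials)


def save_mask_nifti(mask: np.ndarray, voxel_size_mm: float, path) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nib.save(img, str(path))


def load_mask_nifti(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def derive_seed(master_seed: int, *path: str) -> np.random.Generator:
    """Derive a named random substream from one integer master seed.

    Every stochastic step in the package draws from a generator produced
    here, so a single master seed reproduces a full experiment.  The
    stream name (e.g. ``("subject3", "noise")``) is hashed into the
    :class:`numpy.random.SeedSequence` entropy pool.
    """
    tokens = [int(master_seed)]
    for p in path:
        digest = hashlib.sha256(str(p).encode()).digest()[:4]
        tokens.append(int.from_bytes(digest, "little"))
    return np.random.default_rng(np.random.SeedSequence(tokens))
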