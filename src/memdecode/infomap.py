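"""Information maps and their spatial overlap.

An information map marks, within one ROI, the voxels that carried
decodable memory information: the union over cross-validation folds of
the voxels of every searchlight sphere that scored above chance on that
fold's training data.  Overlap between two maps (e.g. recent vs remote
memories, or the same memories at two timepoints) is measured with the
Dice coefficient and tested against a permutation null that shuffles
the map positions uniformly within the ROI while preserving both map
sizes — the only two quantities the Dice null depends on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import derive_seed
from .decode import DecodingResult
from .searchlight import SphereSet


@dataclass
class InformationMap:
    """Binary mask of discriminative voxels within one ROI.

    ``voxel_indices`` index into the ROI's C-scan voxel order; ``mask``
    (if a geometry mask is supplied) is the corresponding 3D boolean
    volume.
    """

    voxel_indices: np.ndarray
    roi_size: int
    roi_name: str = "ROI"
    empty: bool = False

    @property
    def size(self) -> int:
        return len(self.voxel_indices)

    def to_volume(self, roi_mask: np.ndarray) -> np.ndarray:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if int(roi_mask.sum()) != self.roi_size:
            raise ValueError("ROI mask size does not match the map")
        flat = np.zeros(self.roi_size, dtype=bool)
        flat[self.voxel_indices] = True
        out = np.zeros(roi_mask.shape, dtype=bool)
        out[roi_mask] = flat
        return out


def build_information_map(
    result: DecodingResult,
    spheres: SphereSet,
    roi_name: str = "ROI",
) -> InformationMap:
    """Union over folds of the voxels in spheres that scored above
    chance on that fold.

    Folds where no sphere cleared chance (the decoder fell back to its
    best single sphere) contribute nothing.  If every fold is in that
    situation the map is empty and flagged.
    """
    pieces = [
        fs.voxel_indices for fs in result.feature_sets if not fs.empty
    ]
    if not pieces:
        return InformationMap(
            voxel_indices=np.empty(0, dtype=int),
            roi_size=spheres.n_centers,
            roi_name=roi_name,
            empty=True,
        )
    union = np.unique(np.concatenate(pieces))
    return InformationMap(
        voxel_indices=union,
        roi_size=spheres.n_centers,
        roi_name=roi_name,
        empty=False,
    )


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks on the
    same grid; 0 = disjoint, 1 = identical.  Undefined (error) when both
    masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        raise ValueError("Dice is undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / total


def _dice_from_sizes(n_inter: np.ndarray, a: int, b: int) -> np.ndarray:
    return 2.0 * n_inter / (a + b)


@dataclass
class DiceTestResult:
    """Observed Dice per subject against a size-preserving null."""

    observed: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    per_subject_p: np.ndarray
    t: float
    df: int
    p: float
    direction: str  # "below" or "above" the null
    n_perm: int

    def summary(self) -> dict:
        return {
            "observed_mean": float(np.mean(self.observed)),
            "null_mean": float(np.mean(self.null_mean)),
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "direction": self.direction,
            "n_perm": self.n_perm,
        }


def permutation_overlap_test(
    maps_a: list[InformationMap],
    maps_b: list[InformationMap],
    roi_sizes: list[int] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> DiceTestResult:
    """Test observed map overlap against a within-ROI shuffle null.

    Per subject, the null redraws both maps as uniformly random voxel
    subsets of the ROI with the observed cardinalities and records the
    Dice coefficient (``n_perm`` draws).  The group statistic is a
    two-tailed one-sample t across subjects of (observed − subject's
    null mean) against 0, with the departure direction reported.
    """
    if len(maps_a) != len(maps_b) or not maps_a:
        raise ValueError("need one map pair per subject")
    n_subjects = len(maps_a)
    observed = np.empty(n_subjects)
    null_mean = np.empty(n_subjects)
    null_sd = np.empty(n_subjects)
    per_subject_p = np.empty(n_subjects)
    for i, (ma, mb) in enumerate(zip(maps_a, maps_b)):
        n_roi = ma.roi_size if roi_sizes is None else int(roi_sizes[i])
        if ma.roi_size != mb.roi_size:
            raise ValueError(f"subject {i}: maps live in different ROIs")
        a, b = ma.size, mb.size
        if a > n_roi or b > n_roi:
            raise ValueError(f"subject {i}: map larger than its ROI")
        if a + b == 0:
            raise ValueError(f"subject {i}: both maps empty, Dice undefined")
        inter = len(np.intersect1d(ma.voxel_indices, mb.voxel_indices))
        observed[i] = _dice_from_sizes(np.array(inter), a, b)
        rng = derive_seed(seed, "dice-null", str(i))
        draws = np.empty(n_perm)
        for p in range(n_perm):
            sub_a = rng.choice(n_roi, size=a, replace=False)
            sub_b = rng.choice(n_roi, size=b, replace=False)
            draws[p] = _dice_from_sizes(
                len(np.intersect1d(sub_a, sub_b)), a, b
            )
        null_mean[i] = draws.mean()
        null_sd[i] = draws.std(ddof=1)
        # two-sided permutation p with add-one correction
        more_extreme = np.sum(
            np.abs(draws - draws.mean()) >= abs(observed[i] - draws.mean())
        )
        per_subject_p[i] = (more_extreme + 1) / (n_perm + 1)
    diffs = observed - null_mean
    if n_subjects >= 2:
        t, p = stats.ttest_1samp(diffs, 0.0, alternative="two-sided")
    else:
        t, p = np.nan, np.nan  # group test needs >= 2 subjects
    direction = "below" if diffs.mean() < 0 else "above"
    return DiceTestResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        per_subject_p=per_subject_p,
        t=float(t),
        df=n_subjects - 1,
        p=float(p),
        direction=direction,
        n_perm=n_perm,
    )
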