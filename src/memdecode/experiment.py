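"""End-to-end simulated experiments.

:func:`run_experiment` simulates a cohort of subjects (each with one or
two "studies" sharing a single ground truth), runs preprocessing,
searchlight-selected ECOC-SVM decoding and information-map construction
per ROI and memory condition, and applies the group statistics: one-
tailed t against the 1/3 chance level for every (ROI, condition,
study) cell, two-tailed paired t for configured contrasts, a 2x2
within-subject study-by-condition interaction where requested, and
Dice permutation tests for configured information-map pairs.

Every stochastic step derives its stream from the one master seed, so a
report regenerates bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import derive_seed
from .decode import cross_validate
from .infomap import build_information_map, permutation_overlap_test
from .preprocess import PreprocConfig, preprocess
from .searchlight import enumerate_spheres
from .stats import interaction_2x2_within, t_one_sample, t_paired
from .synthetic import DesignSpec, simulate_subject


#: A cell is one (roi, condition, study) accuracy; contrasts compare two.
Cell = tuple[str, str, int]


@dataclass
class ExperimentConfig:
    """Configuration of a simulated cohort analysis.

    ``amplitudes`` maps (ROI, condition) to planted signal scale (or a
    scalar for all); ``contrasts`` lists pairs of (roi, condition,
    study) cells compared with paired t-tests; ``interactions`` lists
    2x2 designs ((cellA1, cellA2), (cellB1, cellB2)); ``dice_pairs``
    lists pairs of cells whose information maps are Dice-tested.
    """

    n_subjects: int = 10
    grid_shape: tuple[int, int, int] = (10, 10, 12)
    roi_size_targets: dict[str, int] = field(default_factory=lambda: {"HC": 64})
    design: DesignSpec = field(default_factory=DesignSpec)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    amplitudes: dict[tuple[str, str], float] | float = 1.0
    support_overlap: float = 1.0
    timepoint_overlap: float = 1.0
    support_fraction: float = 0.4
    noise_sd: float = 1.0
    drift_slope: float = 0.05
    n_studies: int = 1
    decode_rois: list[str] | None = None       # default: all ROIs
    decode_conditions: list[str] | None = None  # default: all conditions
    searchlight_radius: float = 3.0
    selection_alpha: float = 0.05
    roi_elongation: dict[str, float] | None = None
    k: int = 10
    C: float = 1.0
    inner_k: int = 5
    n_perm: int = 1000
    contrasts: list[tuple[Cell, Cell]] = field(default_factory=list)
    interactions: list[tuple[tuple[Cell, Cell], tuple[Cell, Cell]]] = field(
        default_factory=list
    )
    dice_pairs: list[tuple[Cell, Cell]] = field(default_factory=list)


def run_experiment(config: ExperimentConfig, seed: int) -> dict:
    """Simulate, decode and test a full cohort; returns the report.

    The report holds the per-subject accuracy table (also as a
    :class:`pandas.DataFrame` under ``"accuracy_table"``), the
    chance-level tests, contrast and interaction statistics, Dice test
    summaries, the number of tests run (no multiplicity correction is
    applied) and the master seed.
    """
    rois = config.decode_rois or list(config.roi_size_targets)
    conditions = config.decode_conditions or list(config.design.conditions)
    rows = []
    info_maps: dict[Cell, list] = {}
    for s in range(config.n_subjects):
        sub_rng = derive_seed(seed, "subject", str(s))
        subject_seed = int(sub_rng.integers(2**31))
        subject = simulate_subject(
            config.design,
            grid_shape=config.grid_shape,
            roi_size_targets=config.roi_size_targets,
            seed=subject_seed,
            amplitudes=config.amplitudes,
            support_overlap=config.support_overlap,
            timepoint_overlap=config.timepoint_overlap,
            support_fraction=config.support_fraction,
            noise_sd=config.noise_sd,
            drift_slope=config.drift_slope,
            n_studies=config.n_studies,
            elongation=config.roi_elongation,
        )
        sphere_sets = {
            roi: enumerate_spheres(
                subject.geometry.roi_masks[roi], config.searchlight_radius
            )
            for roi in rois
        }
        for study in range(config.n_studies):
            for roi in rois:
                pats = preprocess(
                    subject.bold[study],
                    subject.schedules[study],
                    subject.geometry.roi_masks[roi],
                    config.preproc,
                    roi_name=roi,
                )
                for cond in conditions:
                    cond_pats = pats.subset_condition(cond)
                    result = cross_validate(
                        cond_pats,
                        sphere_sets[roi],
                        k=config.k,
                        C=config.C,
                        seed=subject_seed,
                        inner_k=config.inner_k,
                        selection_alpha=config.selection_alpha,
                    )
                    rows.append(
                        {
                            "subject": s,
                            "roi": roi,
                            "condition": cond,
                            "study": study,
                            "accuracy": result.mean_accuracy,
                            "chance": result.chance,
                            "n_trials": cond_pats.n_trials,
                        }
                    )
                    info_maps.setdefault((roi, cond, study), []).append(
                        build_information_map(
                            result, sphere_sets[roi], roi_name=roi
                        )
                    )
    table = pd.DataFrame(rows)

    n_tests = 0
    chance_tests = {}
    for (roi, cond, study), cell in table.groupby(["roi", "condition", "study"]):
        t, df, p = t_one_sample(cell["accuracy"], cell["chance"].iloc[0])
        chance_tests[f"{roi}/{cond}/study{study}"] = {
            "t": t,
            "df": df,
            "p": p,
            "test": "one-sample t vs chance, one-tailed (greater)",
            "mean_accuracy": float(cell["accuracy"].mean()),
        }
        n_tests += 1

    def cell_values(cell: Cell) -> np.ndarray:
        roi, cond, study = cell
        sel = table[
            (table["roi"] == roi)
            & (table["condition"] == cond)
            & (table["study"] == study)
        ].sort_values("subject")
        return sel["accuracy"].to_numpy()

    contrast_tests = {}
    for cell_a, cell_b in config.contrasts:
        t, df, p = t_paired(cell_values(cell_a), cell_values(cell_b))
        contrast_tests[f"{cell_a} vs {cell_b}"] = {
            "t": t,
            "df": df,
            "p": p,
            "test": "paired t, two-tailed",
            "mean_a": float(np.mean(cell_values(cell_a))),
            "mean_b": float(np.mean(cell_values(cell_b))),
        }
        n_tests += 1

    interaction_tests = {}
    for (a1, a2), (b1, b2) in config.interactions:
        f, df1, df2, p = interaction_2x2_within(
            cell_values(a1), cell_values(a2), cell_values(b1), cell_values(b2)
        )
        interaction_tests[f"({a1}-{a2}) x ({b1}-{b2})"] = {
            "F": f,
            "df1": df1,
            "df2": df2,
            "p": p,
            "test": "2x2 within-subject interaction",
        }
        n_tests += 1

    dice_tests = {}
    for cell_a, cell_b in config.dice_pairs:
        pairs = [
            (ma, mb)
            for ma, mb in zip(info_maps[cell_a], info_maps[cell_b])
            if ma.size + mb.size > 0  # Dice undefined when both are empty
        ]
        n_dropped = len(info_maps[cell_a]) - len(pairs)
        result = permutation_overlap_test(
            [p[0] for p in pairs],
            [p[1] for p in pairs],
            n_perm=config.n_perm,
            seed=seed,
        )
        summary = result.summary()
        summary["n_subjects_dropped_empty"] = n_dropped
        dice_tests[f"{cell_a} vs {cell_b}"] = summary
        n_tests += 1

    return {
        "seed": seed,
        "n_subjects": config.n_subjects,
        "accuracy_table": table,
        "chance_tests": chance_tests,
        "contrast_tests": contrast_tests,
        "interaction_tests": interaction_tests,
        "dice_tests": dice_tests,
        "n_tests_run": n_tests,
        "notes": "p-values are uncorrected; threshold p<0.05 assumed",
    }


def report_to_json(report: dict, path=None) -> str:
    payload = dict(report)
    payload["accuracy_table"] = report["accuracy_table"].to_dict(orient="records")
    text = json.dumps(payload, indent=1, default=str)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def report_to_text(report: dict) -> str:
    lines = [f"simulated cohort: n={report['n_subjects']}, seed={report['seed']}"]
    lines.append("\naccuracy vs chance (one-tailed):")
    for name, r in report["chance_tests"].items():
        lines.append(
            f"  {name}: mean={r['mean_accuracy']:.3f} "
            f"t({r['df']})={r['t']:.3f} p={r['p']:.4f}"
        )
    if report["contrast_tests"]:
        lines.append("\npaired contrasts (two-tailed):")
        for name, r in report["contrast_tests"].items():
            lines.append(
                f"  {name}: {r['mean_a']:.3f} vs {r['mean_b']:.3f} "
                f"t({r['df']})={r['t']:.3f} p={r['p']:.4f}"
            )
    if report["interaction_tests"]:
        lines.append("\ninteractions:")
        for name, r in report["interaction_tests"].items():
            lines.append(
                f"  {name}: F({r['df1']},{r['df2']})={r['F']:.3f} p={r['p']:.4f}"
            )
    if report["dice_tests"]:
        lines.append("\ninformation-map overlap (Dice vs permutation null):")
        for name, r in report["dice_tests"].items():
            lines.append(
                f"  {name}: observed={r['observed_mean']:.3f} "
                f"null={r['null_mean']:.3f} t({r['df']})={r['t']:.3f} "
                f"p={r['p']:.4f} direction={r['direction']}"
            )
    lines.append(f"\ntests run (uncorrected): {report['n_tests_run']}")
    return "\n".join(lines)
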