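"""Grid search over preprocessing parameters on a control cohort.

Every (high-pass, low-pass, detrend, short-channel strategy) combination is
run through the identical downstream GLM; the objective counts participants
with at least one significant HbO channel in the frontal / supplementary
motor cortices (parietal and tongue-motor channels do not count toward the
objective). Patient data must never enter the search: `apply_best_config`
refuses recordings whose ids were seen during optimization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import pandas as pd

from .detect import (DetectionConfig, PreparedRecording, SubjectDecision,
                     detect_prepared, prepare_recording)
from .errors import ParameterError
from .preprocess import FilterSpec
from .recording import Recording

OBJECTIVE_ROI_SET = ("frontal", "sma")


@dataclass(frozen=True)
class Grid:
    """Preprocessing parameter grid.

    The two cutoff lists follow the drift-removal reading: {0, 0.005, 0.01} Hz
    are high-pass (0 = none) and {0.1 .. 1} Hz are low-pass. Set
    ``swap_cutoff_labels=True`` to exchange the two lists.
    """

    highpass_values: tuple[float, ...] = (0.0, 0.005, 0.01)
    lowpass_values: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 1.0)
    detrend_values: tuple[bool, ...] = (True, False)
    strategies: tuple[str, ...] = ("nearest", "all", "pca")
    swap_cutoff_labels: bool = False

    def configurations(self) -> list[tuple[float, float, bool, str]]:
        hp, lp = self.highpass_values, self.lowpass_values
        if self.swap_cutoff_labels:
            hp, lp = lp, hp
        combos = [(h, l, d, s) for h, l, d, s in
                  itertools.product(hp, lp, self.detrend_values, self.strategies)
                  if l == 0 or h < l]  # lowpass 0 = no low-pass stage
        if not combos:
            raise ParameterError("grid contains no valid highpass < lowpass pair")
        return combos


@dataclass
class GridResult:
    table: pd.DataFrame  # one row per configuration
    best_config: DetectionConfig
    best_row: dict
    tie_break_trace: list[dict]
    control_ids: frozenset[str]


def _config_for(base: DetectionConfig, hp: float, lp: float, detrend: bool,
                strategy: str) -> DetectionConfig:
    spec = FilterSpec(highpass_cutoff=hp, lowpass_cutoff=lp, detrend=detrend,
                      order=base.filter_spec.order)
    return replace(base, filter_spec=spec, short_channel_strategy=strategy)


def _objective(decision: SubjectDecision) -> tuple[bool, int, list[str]]:
    """(counts toward objective, number of significant ROI channels, their ROIs).

    Only frontal / SMA channels enter the count; parietal (and tongue-motor)
    significances never do.
    """
    sig = [r for r in decision.channel_results
           if r.chromophore == "HbO" and r.significant
           and r.roi in OBJECTIVE_ROI_SET]
    return (len(sig) > 0, len(sig), sorted({r.roi for r in sig}))


def grid_search(control_recordings: list[Recording], grid: Grid,
                detection_config: DetectionConfig | None = None) -> GridResult:
    """Evaluate every grid configuration on the control cohort.

    Deterministic for fixed inputs and invariant to cohort ordering; the
    filter-independent pipeline stages (QC, OD, TDDR, MBLL) are computed once
    per recording and reused across configurations.
    """
    if not control_recordings:
        raise ParameterError("at least one control recording required")
    base = detection_config or DetectionConfig()
    prepared: list[PreparedRecording] = [prepare_recording(r, base)
                                         for r in control_recordings]
    rows = []
    for hp, lp, detrend, strategy in grid.configurations():
        cfg = _config_for(base, hp, lp, detrend, strategy)
        # the objective only reads HbO results; skip the HbR fits in the sweep
        cfg_eval = replace(cfg, chromophores=("HbO",)) \
            if cfg.sign_rule == "hbo_positive" else cfg
        per_subject = []
        for prep in prepared:
            dec = detect_prepared(prep, cfg_eval)
            counts, n_sig, rois = _objective(dec)
            per_subject.append({"subject_id": prep.subject_id,
                                "counts": counts, "n_sig_roi": n_sig,
                                "counted_rois": rois})
        per_subject.sort(key=lambda s: s["subject_id"])
        rows.append({
            "highpass": hp, "lowpass": lp, "detrend": detrend,
            "strategy": strategy,
            "objective": sum(s["counts"] for s in per_subject),
            "total_sig_roi_channels": sum(s["n_sig_roi"] for s in per_subject),
            "per_subject": per_subject,
        })
    table = pd.DataFrame(rows)

    # tie-break: max objective, then max total significant ROI channels, then
    # lexicographically smallest (highpass, lowpass, detrend, strategy)
    def sort_key(row):
        return (-row["objective"], -row["total_sig_roi_channels"],
                row["highpass"], row["lowpass"], row["detrend"], row["strategy"])

    ordered = sorted(rows, key=sort_key)
    best = ordered[0]
    trace = [{k: r[k] for k in ("highpass", "lowpass", "detrend", "strategy",
                                "objective", "total_sig_roi_channels")}
             for r in ordered[:5]]
    best_cfg = _config_for(base, best["highpass"], best["lowpass"],
                           best["detrend"], best["strategy"])
    return GridResult(table, best_cfg, best, trace,
                      frozenset(r.subject_id for r in control_recordings))


def apply_best_config(patient_recordings: list[Recording],
                      grid_result: GridResult) -> list[SubjectDecision]:
    """Run detection on patients exactly once with the optimized configuration.

    Raises if any patient id was part of the control cohort used for the
    search (leakage guard).
    """
    leaked = [r.subject_id for r in patient_recordings
              if r.subject_id in grid_result.control_ids]
    if leaked:
        raise ParameterError(
            f"patient recordings {leaked} were used during grid search")
    cfg = grid_result.best_config
    return [detect_prepared(prepare_recording(r, cfg), cfg)
            for r in patient_recordings]
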