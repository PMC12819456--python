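"""Subject-level detection of volitional activation.

Chains the preprocessing pipeline into a per-channel prewhitened robust GLM
with short-channel nuisance regression, BH-FDR across long channels, a
positive-HbO sign rule, and the subject / patient-level activation decision.
Also provides a formalized proxy for the bedside visual rating procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glm import (ar_prewhiten, build_design_matrix, fdr_bh, robust_glm,
                  short_channel_regressors)
from .hrf import boxcar
from .preprocess import (ExcludedRecording, ExtinctionModel, FilterSpec,
                         HemoSeries, apply_filter, apply_qc, channel_qc,
                         filter_array, intensity_to_od, od_to_concentration,
                         tddr)
from .recording import EventSchedule, Probe, Recording

DEFAULT_ROI_SET = ("frontal", "sma", "tongue_motor")


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of the detection pipeline."""

    q_threshold: float = 0.05
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    short_channel_strategy: str = "nearest"  # nearest | all | pca
    sign_rule: str = "hbo_positive"  # or "hbo_positive_and_hbr_negative"
    roi_set: tuple[str, ...] = DEFAULT_ROI_SET
    ar_max_order: int = 8
    ar_ic: str = "bic"
    tukey_c: float = 4.685
    add_drift_column: bool = False
    run_qc: bool = True
    run_tddr: bool = True
    #: pass the task regressor through each channel's fitted TDDR operator so
    #: the motion-correction amplitude transfer does not bias the task beta
    tddr_matched_regressor: bool = True
    snr_threshold: float = 8.0
    max_bad_fraction: float = 0.5
    pca_variance: float = 0.9
    extinction: ExtinctionModel = field(default_factory=ExtinctionModel)
    #: chromophores to fit; the decision only needs HbO unless the sign rule
    #: demands HbR corroboration
    chromophores: tuple[str, ...] = ("HbO", "HbR")
    #: the GLM runs on data decimated (after low-pass filtering) so that the
    #: decimated rate is ~decim_margin x (2 x lowpass cutoff)
    decim_margin: float = 1.25

    def validate(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")
        if self.ar_max_order < 0:
            raise ValueError("ar_max_order must be >= 0")


@dataclass
class ChannelResult:
    channel: str
    chromophore: str  # "HbO" or "HbR"
    roi: str
    beta: float
    se: float
    t_value: float
    p_value: float
    q_value: float
    significant: bool


@dataclass
class SubjectDecision:
    subject_id: str
    session_index: int
    activation_present: bool
    indeterminate: bool
    channel_results: list[ChannelResult]
    roi_summary: dict[str, int]

    @property
    def significant_channels(self) -> list[ChannelResult]:
        return [r for r in self.channel_results if r.significant]


def combine_sessions(decisions: list[SubjectDecision]) -> dict:
    """Patient-level verdict over up to three sessions: positive iff any
    session is positive; indeterminate only when every session is."""
    if not decisions:
        raise ValueError("no session decisions to combine")
    usable = [d for d in decisions if not d.indeterminate]
    return {
        "any_session_positive": any(d.activation_present for d in usable),
        "indeterminate": len(usable) == 0,
        "n_sessions": len(decisions),
    }


@dataclass
class PreparedRecording:
    """Filter-independent part of the pipeline (QC, OD, TDDR, MBLL), cached so
    the optimizer can sweep filter settings without redoing motion correction."""

    hemo_long: HemoSeries
    hemo_short: HemoSeries
    events: EventSchedule
    sampling_rate: float
    subject_id: str
    session_index: int
    probe: Probe | None = None
    excluded: ExcludedRecording | None = None
    #: per-chromophore, per-long-channel task regressors matched to the TDDR
    #: correction actually applied to that channel (None when TDDR is off)
    matched_task: dict[str, dict[str, np.ndarray]] | None = None


def prepare_recording(recording: Recording, config: DetectionConfig) -> PreparedRecording:
    """Run QC, OD conversion, TDDR and MBLL; drop bad channels."""
    probe = recording.probe
    if config.run_qc:
        qc = channel_qc(recording, snr_threshold=config.snr_threshold,
                        max_bad_fraction=config.max_bad_fraction)
        res = apply_qc(recording, qc, config.max_bad_fraction)
        if isinstance(res, ExcludedRecording):
            empty = HemoSeries(np.zeros((0, 0)), np.zeros((0, 0)),
                               recording.sampling_rate, ())
            return PreparedRecording(empty, empty, recording.events,
                                     recording.sampling_rate,
                                     recording.subject_id,
                                     recording.session_index, probe=probe,
                                     excluded=res)
        recording = res
    bad = set(recording.meta.get("bad_channels", []))

    od = intensity_to_od(recording)
    matched_task = None
    if config.run_tddr:
        if config.tddr_matched_regressor:
            od, ops = tddr(od, return_operators=True)
            matched_task = _matched_task_regressors(recording, config, ops, bad)
        else:
            od = tddr(od)
    hemo_long = od_to_concentration(od, probe, config.extinction, "long")
    hemo_short = od_to_concentration(od, probe, config.extinction, "short")

    def drop(hemo: HemoSeries) -> HemoSeries:
        keep = [i for i, ch in enumerate(hemo.channels) if ch.name not in bad]
        return HemoSeries(hemo.hbo[:, keep], hemo.hbr[:, keep],
                          hemo.sampling_rate,
                          tuple(hemo.channels[i] for i in keep))

    return PreparedRecording(drop(hemo_long), drop(hemo_short),
                             recording.events, recording.sampling_rate,
                             recording.subject_id, recording.session_index,
                             probe=probe, matched_task=matched_task)


def _matched_task_regressors(recording: Recording, config: DetectionConfig,
                             ops: dict, bad: set[str]
                             ) -> dict[str, dict[str, np.ndarray]]:
    """Push the canonical task regressor through each long channel's fitted
    TDDR operators (per wavelength) and recombine through the MBLL inverse,
    giving the regressor exactly the amplitude transfer the data received."""
    from .hrf import task_regressor

    probe = recording.probe
    reg = task_regressor(recording.events, recording.sampling_rate,
                         recording.n_samples)
    eps = np.asarray(config.extinction.epsilon, float)
    inv = config.extinction.inverse
    out: dict[str, dict[str, np.ndarray]] = {"hbo": {}, "hbr": {}}
    for ch in probe.long_channels:
        if ch.name in bad:
            continue
        ci = probe.channel_index(ch.name)
        t760 = ops[(ci, 0)].apply(reg)
        t850 = ops[(ci, 1)].apply(reg)
        for k, chrom in enumerate(("hbo", "hbr")):
            out[chrom][ch.name] = (inv[k, 0] * eps[0, k] * t760
                                   + inv[k, 1] * eps[1, k] * t850)
    return out


def _decimation_factor(sampling_rate: float, spec: FilterSpec, margin: float) -> int:
    if spec.lowpass_cutoff <= 0:  # no anti-alias bound: keep the full rate
        return 1
    return max(1, int(sampling_rate / (margin * 2.0 * spec.lowpass_cutoff)))


def detect_prepared(prep: PreparedRecording, config: DetectionConfig) -> SubjectDecision:
    """Filter, decimate, fit the per-channel prewhitened robust GLM, apply
    BH-FDR over long-channel HbO p-values and the sign rule, and decide."""
    config.validate()
    if prep.excluded is not None or len(prep.hemo_long.channels) == 0:
        return SubjectDecision(prep.subject_id, prep.session_index,
                               activation_present=False, indeterminate=True,
                               channel_results=[], roi_summary={})
    spec = config.filter_spec
    fs = prep.sampling_rate
    long_f = apply_filter(prep.hemo_long, spec)
    short_f = apply_filter(prep.hemo_short, spec) \
        if len(prep.hemo_short.channels) else prep.hemo_short

    n = long_f.hbo.shape[0]
    dm = build_design_matrix(prep.events, fs, n,
                             add_drift=config.add_drift_column)
    # the task regressor passes through the same filter as the data so that
    # band attenuation does not bias the task coefficient
    task_filtered = filter_array(dm.column("task"), spec, fs)

    step = _decimation_factor(fs, spec, config.decim_margin)
    sl = slice(None, None, step)
    intercept = np.ones(len(long_f.hbo[sl, 0]))
    drift_col = dm.column("drift")[sl] if config.add_drift_column else None

    chromophores = tuple(config.chromophores)
    if config.sign_rule == "hbo_positive_and_hbr_negative" and "HbR" not in chromophores:
        chromophores = chromophores + ("HbR",)

    matched_cols: dict[tuple[str, str], np.ndarray] = {}
    if prep.matched_task is not None:
        keys = [(chrom.lower(), name) for chrom in chromophores
                for name in prep.matched_task[chrom.lower()]]
        if keys:
            stacked = np.column_stack([prep.matched_task[c][nm] for c, nm in keys])
            filt = filter_array(stacked, spec, fs)
            matched_cols = {key: filt[sl, k] for k, key in enumerate(keys)}

    def task_column(chrom: str, name: str) -> np.ndarray:
        return matched_cols.get((chrom, name), task_filtered[sl])

    nuis = {"hbo": {}, "hbr": {}}
    if len(short_f.channels):
        for chrom in (c.lower() for c in chromophores):
            nuis[chrom] = short_channel_regressors(
                short_f, prep.probe, config.short_channel_strategy,
                long_channels=long_f.channels, chromophore=chrom,
                pca_variance=config.pca_variance)

    results: list[ChannelResult] = []
    per_chrom: dict[str, list[dict]] = {"HbO": [], "HbR": []}
    # keep 10 samples per AR coefficient on short records
    ar_order = min(config.ar_max_order, max(0, (len(intercept) - 1) // 10))
    series_by_chrom = {"HbO": long_f.hbo, "HbR": long_f.hbr}
    for j, ch in enumerate(long_f.channels):
        for chrom in chromophores:
            series = series_by_chrom[chrom]
            y = series[sl, j]
            parts = [intercept, task_column(chrom.lower(), ch.name)]
            if drift_col is not None:
                parts.append(drift_col)
            X = np.column_stack(parts)
            block = nuis[chrom.lower()].get(ch.name)
            if block is not None:
                X = np.column_stack([X, np.asarray(block)[sl]])
            yw, Xw, _ = ar_prewhiten(y, X, ar_order, config.ar_ic)
            fit = robust_glm(yw, Xw, tukey_c=config.tukey_c)
            per_chrom[chrom].append({
                "channel": ch.name, "roi": ch.roi,
                "beta": float(fit["beta"][1]), "se": float(fit["se"][1]),
                "t": float(fit["t"][1]), "p": float(fit["p"][1])})

    hbr_by_channel = {r["channel"]: r for r in per_chrom["HbR"]}
    for chrom in chromophores:
        rows = per_chrom[chrom]
        q, _ = fdr_bh([r["p"] for r in rows], config.q_threshold)
        for r, qv in zip(rows, q):
            if chrom == "HbO":
                sig = qv < config.q_threshold and r["beta"] > 0
                if sig and config.sign_rule == "hbo_positive_and_hbr_negative":
                    sig = hbr_by_channel[r["channel"]]["beta"] < 0
            else:
                sig = qv < config.q_threshold and r["beta"] < 0
            results.append(ChannelResult(r["channel"], chrom, r["roi"],
                                         r["beta"], r["se"], r["t"], r["p"],
                                         float(qv), bool(sig)))

    sig_hbo = [r for r in results if r.chromophore == "HbO" and r.significant]
    roi_summary: dict[str, int] = {}
    for r in sig_hbo:
        roi_summary[r.roi] = roi_summary.get(r.roi, 0) + 1
    present = any(r.roi in config.roi_set for r in sig_hbo)
    return SubjectDecision(prep.subject_id, prep.session_index,
                           activation_present=present, indeterminate=False,
                           channel_results=results, roi_summary=roi_summary)


def detect_subject(recording: Recording,
                   config: DetectionConfig | None = None) -> SubjectDecision:
    """Full pipeline: QC -> OD -> TDDR -> MBLL -> filter -> GLM -> decision."""
    config = config or DetectionConfig()
    return detect_prepared(prepare_recording(recording, config), config)


def formal_bedside_rule(hemo: HemoSeries, events: EventSchedule,
                        roi_set: tuple[str, ...] = ("tongue_motor", "sma"),
                        r_threshold: float = 0.3, contrast_mult: float = 2.0,
                        hrf_lag: float = 5.0) -> bool:
    """Formalized proxy for the bedside visual rating (not the human procedure).

    A channel "lights up" when (a) its HbO trace correlates with the
    HRF-lag-shifted task indicator (r > ``r_threshold``) and (b) its peak
    task-window activation exceeds ``contrast_mult`` x the rest-period SD.
    The rule returns True iff at least one such channel lies in ``roi_set``
    and no activation pattern exists only outside it.
    """
    fs = hemo.sampling_rate
    n = hemo.hbo.shape[0]
    t = np.arange(n) / fs
    box = boxcar(events, fs, n)
    lag = int(round(hrf_lag * fs))
    shifted = np.concatenate([np.zeros(lag), box])[:n]
    rest_mask = np.ones(n, bool)
    for ep in events.task_epochs:
        rest_mask[(t >= ep.onset) & (t < ep.offset + hrf_lag)] = False

    passing = []
    for j, ch in enumerate(hemo.channels):
        y = hemo.hbo[:, j]
        if np.std(y) == 0 or np.std(shifted) == 0:
            continue
        r = np.corrcoef(y, shifted)[0, 1]
        base_sd = np.std(y[rest_mask]) if rest_mask.any() else np.std(y)
        window_peaks = []
        for ep in events.task_epochs:
            m = (t >= ep.onset + hrf_lag) & (t < ep.offset + hrf_lag)
            if m.any():
                window_peaks.append(np.mean(y[m]))
        contrast = max(window_peaks) if window_peaks else 0.0
        if r > r_threshold and base_sd > 0 and contrast >= contrast_mult * base_sd:
            passing.append(ch)
    if not passing:
        return False
    return any(ch.roi in roi_set for ch in passing)
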