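"""Intensity -> optical density -> hemoglobin concentration preprocessing chain.

Implements the standard continuous-wave fNIRS chain: optical-density
conversion, temporal derivative distribution repair (TDDR) motion correction,
the modified Beer-Lambert law (MBLL), zero-phase Butterworth band filtering,
and channel / recording quality control (SNR and cardiac-rhythm checks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ModelError, ParameterError, ValidationError
from .recording import Channel, Probe, Recording

# Extinction coefficients epsilon(lambda, chromophore) in cm^-1 uM^-1 for
# lambda in (760, 850) nm and chromophores (HbO, HbR), from the standard
# compiled hemoglobin absorption tabulation (Prahl); rows are wavelengths.
DEFAULT_EXTINCTION = np.array([
    [1486.5865, 3843.707],
    [2526.391, 1798.643],
]) * 1e-6


@dataclass(frozen=True)
class ExtinctionModel:
    """MBLL coefficients: extinction matrix, differential pathlength factors."""

    epsilon: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())
    dpf: tuple[float, float] = (6.0, 6.0)  # per wavelength, dimensionless

    def validate(self) -> None:
        eps = np.asarray(self.epsilon, float)
        if eps.shape != (2, 2):
            raise ModelError("epsilon must be 2x2")
        if np.linalg.cond(eps) >= 100:
            raise ModelError("extinction matrix is ill-conditioned")
        if any(d <= 0 for d in self.dpf):
            raise ModelError("dpf must be positive")

    @property
    def inverse(self) -> np.ndarray:
        self.validate()
        return np.linalg.inv(np.asarray(self.epsilon, float))


@dataclass
class ODSeries:
    """Dimensionless optical-density changes, shape (T, n_channels, 2)."""

    values: np.ndarray
    sampling_rate: float

    def validate(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("OD contains non-finite values")


@dataclass
class HemoSeries:
    """Chromophore concentration changes (uM) for a subset of channels."""

    hbo: np.ndarray  # (T, n_channels)
    hbr: np.ndarray
    sampling_rate: float
    channels: tuple[Channel, ...]

    def validate(self) -> None:
        if self.hbo.shape != self.hbr.shape or self.hbo.shape[1] != len(self.channels):
            raise ValidationError("HemoSeries shape mismatch")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ValidationError("HemoSeries contains non-finite values")

    def channel_names(self) -> list[str]:
        return [ch.name for ch in self.channels]


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth band specification.

    A cutoff of 0 disables that stage (either one); ``detrend`` removes a
    best-fit line first.
    """

    highpass_cutoff: float = 0.01  # Hz, 0 = none
    lowpass_cutoff: float = 0.2  # Hz, 0 = none
    detrend: bool = True
    order: int = 3

    def validate(self, sampling_rate: float) -> None:
        if self.highpass_cutoff < 0 or self.lowpass_cutoff < 0:
            raise ParameterError("cutoffs must be non-negative")
        if self.lowpass_cutoff > 0 and self.highpass_cutoff >= self.lowpass_cutoff:
            raise ParameterError(
                f"highpass_cutoff ({self.highpass_cutoff}) must lie below "
                f"lowpass_cutoff ({self.lowpass_cutoff})")
        for name, cut in [("lowpass_cutoff", self.lowpass_cutoff),
                          ("highpass_cutoff", self.highpass_cutoff)]:
            if cut >= sampling_rate / 2:
                raise ParameterError(
                    f"{name} ({cut} Hz) must be below the Nyquist frequency "
                    f"({sampling_rate / 2} Hz)")
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")


@dataclass
class ChannelQC:
    name: str
    snr: float
    cardiac_present: bool
    is_good: bool


@dataclass
class QCReport:
    channels: list[ChannelQC]
    bad_fraction: float
    recording_excluded: bool

    def good_names(self) -> set[str]:
        return {c.name for c in self.channels if c.is_good}


@dataclass
class ExcludedRecording:
    """Marker returned when a recording fails whole-recording quality control."""

    subject_id: str
    session_index: int
    bad_fraction: float


def intensity_to_od(recording: Recording) -> ODSeries:
    """OD(t) = -ln(I(t) / mean(I)) per channel and wavelength."""
    inten = np.asarray(recording.intensity, float)
    if np.any(inten <= 0):
        t, c, w = np.unravel_index(np.argmin(inten), inten.shape)
        raise ValidationError(
            f"non-positive intensity at sample {t}, channel "
            f"{recording.probe.channels[c].name}, wavelength index {w}")
    od = -np.log(inten / inten.mean(axis=0, keepdims=True))
    return ODSeries(od, recording.sampling_rate)


@dataclass(frozen=True)
class TddrOperator:
    """The linear operator a converged TDDR fit applies to a small
    superimposed signal: split at 0.5 Hz, multiply the (trend-centered)
    low-frequency derivative by the fitted weights, re-integrate.

    Passing a GLM regressor through this operator matches it to the
    motion-corrected data exactly the way a band filter applied to both data
    and regressors does, so TDDR's amplitude transfer does not bias the task
    coefficient.
    """

    weights: np.ndarray  # (n_samples - 1,)
    sampling_rate: float

    def apply(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, float)
        low, high = _tddr_split(v, self.sampling_rate)
        d = np.diff(low)
        w = self.weights
        mu = np.sum(w * d) / np.sum(w)
        corrected = np.concatenate([[0.0], np.cumsum(w * (d - mu))])
        return corrected + high + low[0]


def _tddr_split(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    if fs > 1.0:
        sos = signal.butter(3, 0.5 / (fs / 2), btype="low", output="sos")
        low = signal.sosfiltfilt(sos, x)
    else:
        low = x.copy()
    return low, x - low


def _tddr_trace(x: np.ndarray, fs: float, tune: float = 4.685,
                tol: float = 1e-8, max_iter: int = 50
                ) -> tuple[np.ndarray, np.ndarray]:
    """TDDR on one trace: robustly reweight the first differences of the
    sub-0.5 Hz component and re-integrate, leaving the high-frequency part.
    Returns the corrected trace and the converged weights."""
    x = np.asarray(x, float)
    if np.ptp(x) == 0:
        return x.copy(), np.ones(max(len(x) - 1, 0))
    low, high = _tddr_split(x, fs)

    d = np.diff(low)
    w = np.ones_like(d)
    mu = 0.0
    for _ in range(max_iter):
        mu = np.sum(w * d) / np.sum(w)
        dev = d - mu
        sigma = 1.4826 * np.median(np.abs(dev))
        if sigma == 0:
            break
        r = dev / (tune * sigma)
        w_new = np.where(np.abs(r) < 1, (1 - r**2) ** 2, 0.0)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    corrected = np.concatenate([[0.0], np.cumsum(w * (d - mu))])
    return corrected + high + low[0], w


def tddr(od: ODSeries, return_operators: bool = False):
    """Temporal derivative distribution repair, applied per channel x wavelength.

    With ``return_operators=True`` also returns the per-trace
    :class:`TddrOperator` (indexed by (channel, wavelength)) so regressors can
    be passed through the identical correction.
    """
    vals = np.asarray(od.values, float)
    if vals.shape[0] < 10:
        raise ParameterError("TDDR requires at least 10 samples")
    out = np.empty_like(vals)
    ops: dict[tuple[int, int], TddrOperator] = {}
    for c in range(vals.shape[1]):
        for w in range(vals.shape[2]):
            out[:, c, w], weights = _tddr_trace(vals[:, c, w], od.sampling_rate)
            if return_operators:
                ops[(c, w)] = TddrOperator(weights, od.sampling_rate)
    corrected = ODSeries(out, od.sampling_rate)
    return (corrected, ops) if return_operators else corrected


def forward_od(hbo: np.ndarray, hbr: np.ndarray, separation: float,
               model: ExtinctionModel) -> np.ndarray:
    """Forward MBLL: concentrations (uM) -> OD at (760, 850) nm, shape (T, 2).

    Used by the simulator so that OD -> concentration inverts it exactly.
    """
    eps = np.asarray(model.epsilon, float)
    conc = np.stack([hbo, hbr], axis=-1)  # (T, 2)
    od = conc @ eps.T  # (T, 2) in cm^-1 * uM * (cm^-1 uM^-1) terms
    return od * separation * np.asarray(model.dpf)


def od_to_concentration(od: ODSeries, probe: Probe, model: ExtinctionModel | None = None,
                        which: str = "long") -> HemoSeries:
    """Inverse MBLL: per channel, [dHbO; dHbR] = eps^-1 [OD_l / (d * DPF_l)].

    ``which`` selects the channel subset: "long", "short" or "all".
    """
    model = model or ExtinctionModel()
    inv = model.inverse
    if which == "long":
        chans = probe.long_channels
    elif which == "short":
        chans = probe.short_channels
    elif which == "all":
        chans = probe.channels
    else:
        raise ParameterError(f"unknown channel subset {which!r}")
    idx = [probe.channel_index(ch.name) for ch in chans]
    dpf = np.asarray(model.dpf)
    vals = np.asarray(od.values, float)[:, idx, :]  # (T, k, 2)
    seps = np.array([ch.separation for ch in chans])[None, :, None]
    scaled = vals / (seps * dpf[None, None, :])
    conc = np.einsum("tkw,cw->tkc", scaled, inv)  # c indexes (HbO, HbR)
    return HemoSeries(conc[:, :, 0], conc[:, :, 1], od.sampling_rate, tuple(chans))


def filter_array(x: np.ndarray, spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    """Apply ``spec`` along axis 0 of a 1-D or 2-D array."""
    spec.validate(sampling_rate)
    y = np.asarray(x, float)
    if spec.detrend:
        y = signal.detrend(y, axis=0, type="linear")
    nyq = sampling_rate / 2
    cutoffs = [c for c in (spec.highpass_cutoff, spec.lowpass_cutoff) if c > 0]
    if not cutoffs:
        return y
    # generous padding keeps narrow-band edges from leaking into the record
    padlen = int(min(y.shape[0] - 1, 10 * sampling_rate / min(cutoffs)))
    if spec.highpass_cutoff > 0:
        sos = signal.butter(spec.order, spec.highpass_cutoff / nyq, "high", output="sos")
        y = signal.sosfiltfilt(sos, y, axis=0, padlen=padlen)
    if spec.lowpass_cutoff > 0:
        sos = signal.butter(spec.order, spec.lowpass_cutoff / nyq, "low", output="sos")
        y = signal.sosfiltfilt(sos, y, axis=0, padlen=padlen)
    return y


def apply_filter(hemo: HemoSeries, spec: FilterSpec) -> HemoSeries:
    """Detrend / band-filter both chromophores of a HemoSeries."""
    return HemoSeries(
        filter_array(hemo.hbo, spec, hemo.sampling_rate),
        filter_array(hemo.hbr, spec, hemo.sampling_rate),
        hemo.sampling_rate, hemo.channels)


def _cardiac_present(trace: np.ndarray, fs: float, band: tuple[float, float],
                     peak_factor: float) -> bool:
    # 20 s segments: enough spectral averaging at the 60 s QC minimum while
    # still resolving a cardiac line against the broadband background
    f, pxx = signal.welch(trace - trace.mean(), fs=fs,
                          nperseg=min(len(trace), int(20 * fs)))
    in_band = (f >= band[0]) & (f <= band[1])
    wide = (f >= 0.25) & (f <= 3.0)
    if not np.any(in_band) or not np.any(wide):
        return False
    background = np.median(pxx[wide])
    peak = np.max(pxx[in_band])
    return peak > 0 and peak >= peak_factor * background


def channel_qc(recording: Recording, snr_threshold: float = 8.0,
               cardiac_band: tuple[float, float] = (0.6, 2.0),
               peak_factor: float = 3.0,
               max_bad_fraction: float = 0.5) -> QCReport:
    """Per-channel SNR / cardiac-rhythm quality control on raw intensity.

    SNR is mean/SD of raw intensity (the worse of the two wavelengths); a
    channel is good iff SNR >= ``snr_threshold`` and a cardiac spectral peak
    (local power >= ``peak_factor`` x broadband median within
    ``cardiac_band``) is present at both wavelengths. The recording is
    excluded when the bad fraction among long channels exceeds
    ``max_bad_fraction``.
    """
    if recording.n_samples / recording.sampling_rate < 60:
        raise ParameterError("channel_qc requires at least 60 s of data")
    inten = np.asarray(recording.intensity, float)
    results = []
    for c, ch in enumerate(recording.probe.channels):
        snrs, cardiac = [], []
        for w in range(2):
            trace = inten[:, c, w]
            sd = trace.std()
            if sd == 0:
                snrs.append(np.inf)
                cardiac.append(False)
            else:
                snrs.append(trace.mean() / sd)
                cardiac.append(_cardiac_present(trace, recording.sampling_rate,
                                                cardiac_band, peak_factor))
        snr = min(snrs)
        good = snr >= snr_threshold and all(cardiac)
        results.append(ChannelQC(ch.name, snr, all(cardiac), good))

    long_names = {ch.name for ch in recording.probe.long_channels}
    long_qc = [r for r in results if r.name in long_names]
    bad_fraction = sum(not r.is_good for r in long_qc) / len(long_qc)
    return QCReport(results, bad_fraction, bad_fraction > max_bad_fraction)


def apply_qc(recording: Recording, qc: QCReport,
             max_bad_fraction: float = 0.5) -> Recording | ExcludedRecording:
    """Drop bad channels from downstream analysis or exclude the recording.

    Bad channels are recorded in ``recording.meta['bad_channels']`` (the probe
    itself is left intact so montage invariants keep holding).
    """
    if qc.bad_fraction > max_bad_fraction:
        return ExcludedRecording(recording.subject_id, recording.session_index,
                                 qc.bad_fraction)
    bad = sorted({c.name for c in qc.channels if not c.is_good})
    meta = dict(recording.meta)
    meta["bad_channels"] = bad
    return recording.copy_with(meta=meta)
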