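"""Synthetic block-design fNIRS recordings with known ground truth.

The generator emulates a dual-wavelength (760/850 nm) continuous-wave
acquisition sampled at 10.17 Hz with the default 8-source/15-detector montage
and a 3-block x 8-repetition (15 s task / 15 s rest) schedule. Responder
subjects carry a canonical-HRF-convolved task response (HbO up, HbR down by a
fixed ratio) in the responder ROI channels; every channel additionally carries
white noise, polynomial drift, and a shared superficial systemic component
(cardiac + respiratory + Mayer sinusoids plus a slow random walk) that enters
short channels at full amplitude and long channels at half amplitude.
Concentrations are forward-converted to optical density with the modified
Beer-Lambert law and to intensity as I(t) = I0 * exp(-OD(t)), so the
preprocessing chain inverts the forward model exactly in the noise-free case.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .hrf import task_regressor
from .preprocess import ExtinctionModel, forward_od
from .recording import (EventSchedule, Probe, Recording, build_block_design,
                        default_montage)

# relative weights of the sinusoidal components inside the superficial signal
_CARDIAC_W, _RESP_W, _MAYER_W, _WALK_W = 0.5, 0.3, 0.4, 0.3
# fraction of the superficial HbO signal appearing in long channels / in HbR
_LONG_SUPERFICIAL_FRACTION = 0.5
_HBR_SUPERFICIAL_FRACTION = 0.3
_HBR_NOISE_FRACTION = 0.5


@dataclass(frozen=True)
class SimulationParams:
    """Study-condition parameters of the synthetic acquisition."""

    sampling_rate: float = 10.17  # Hz
    n_blocks: int = 3
    reps_per_block: int = 8
    task_duration: float = 15.0  # s
    rest_duration: float = 15.0  # s
    inter_block_gap: float = 30.0  # s
    lead_in: float = 15.0  # s of baseline before the first block
    hbo_amplitude: float = 0.5  # uM, task response peak (responders only)
    hbr_ratio: float = 1.0 / 3.0  # HbR amplitude = -hbr_ratio * HbO amplitude
    noise_sd: float = 0.1  # uM white noise on HbO
    drift_coeffs: tuple[float, ...] = (0.0, 0.4)  # uM, polynomial in t/T
    cardiac_freq: float = 1.2  # Hz
    resp_freq: float = 0.25  # Hz
    mayer_freq: float = 0.1  # Hz
    superficial_amp: float = 0.5  # uM in short channels
    motion_spike_rate: float = 0.5  # events/min
    motion_shift_rate: float = 0.1  # events/min
    responder_channel_labels: tuple[str, ...] = ("tongue_motor",)
    seed: int = 0

    def validate(self) -> None:
        positive = ["sampling_rate", "n_blocks", "reps_per_block",
                    "task_duration", "rest_duration"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        non_negative = ["inter_block_gap", "lead_in", "hbo_amplitude", "hbr_ratio",
                        "noise_sd", "superficial_amp", "motion_spike_rate",
                        "motion_shift_rate"]
        for name in non_negative:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.sampling_rate <= 2 * self.cardiac_freq:
            raise ParameterError(
                "sampling_rate must exceed twice cardiac_freq")

    def schedule(self) -> EventSchedule:
        return build_block_design(self.n_blocks, self.reps_per_block,
                                  self.task_duration, self.rest_duration,
                                  self.inter_block_gap, self.lead_in)


@dataclass(frozen=True)
class GroundTruth:
    is_responder: bool
    active_channels: frozenset[str]
    true_hbo_amplitude: float
    true_hbr_amplitude: float


@dataclass(frozen=True)
class ArtifactEvent:
    kind: str  # "spike" or "shift"
    trace: int  # flattened trace index
    onset_sample: int
    duration_samples: int  # to end of record for shifts
    amplitude: float


def inject_motion_artifacts(series: np.ndarray, spike_rate: float,
                            shift_rate: float, seed: int,
                            spike_min_mult: float = 5.0,
                            sampling_rate: float = 10.17
                            ) -> tuple[np.ndarray, list[ArtifactEvent]]:
    """Add spike (< 1 s, >= ``spike_min_mult`` x SD) and baseline-shift artifacts.

    Operates along axis 0; trailing axes are treated as independent traces.
    Returns the corrupted copy together with a log of artifact times and
    magnitudes. Rates are in events/min.
    """
    if spike_rate < 0 or shift_rate < 0:
        raise ParameterError("artifact rates must be non-negative")
    x = np.asarray(series, float).copy()
    if spike_rate == 0 and shift_rate == 0:
        return x, []
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    flat = x.reshape(n, -1)
    minutes = n / sampling_rate / 60.0
    events: list[ArtifactEvent] = []
    for k in range(flat.shape[1]):
        sd = flat[:, k].std()
        base = sd if sd > 0 else 1.0
        for _ in range(rng.poisson(spike_rate * minutes)):
            width = int(rng.uniform(0.2, 0.9) * sampling_rate)
            width = max(2, min(width, int(0.99 * sampling_rate)))
            t0 = int(rng.integers(0, max(1, n - width)))
            amp = rng.choice([-1, 1]) * (spike_min_mult + rng.exponential(2.0)) * base
            bump = np.exp(-0.5 * ((np.arange(width) - width / 2) / (width / 5)) ** 2)
            flat[t0:t0 + width, k] += amp * bump
            events.append(ArtifactEvent("spike", k, t0, width, amp))
        for _ in range(rng.poisson(shift_rate * minutes)):
            t0 = int(rng.integers(1, n))
            amp = rng.choice([-1, 1]) * (2.0 + rng.exponential(2.0)) * base
            flat[t0:, k] += amp
            events.append(ArtifactEvent("shift", k, t0, n - t0, amp))
    return flat.reshape(x.shape), events


def _superficial_signal(params: SimulationParams, t: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Shared systemic signal: cardiac/resp/Mayer sinusoids + slow random walk."""
    phases = rng.uniform(0, 2 * np.pi, 3)
    s = (_CARDIAC_W * np.sin(2 * np.pi * params.cardiac_freq * t + phases[0])
         + _RESP_W * np.sin(2 * np.pi * params.resp_freq * t + phases[1])
         + _MAYER_W * np.sin(2 * np.pi * params.mayer_freq * t + phases[2]))
    walk = np.cumsum(rng.standard_normal(len(t)))
    sd = walk.std()
    if sd > 0:
        s = s + _WALK_W * walk / sd
    return params.superficial_amp * s


def simulate_subject(params: SimulationParams,
                     probe: Probe | None = None) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic recording and its ground truth.

    Responder status is determined by ``hbo_amplitude > 0``; active channels
    are the long channels whose ROI is in ``responder_channel_labels``.
    """
    params.validate()
    probe = probe or default_montage()
    events = params.schedule()
    fs = params.sampling_rate
    n = int(round(events.total_duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(params.seed)
    model = ExtinctionModel()

    is_responder = params.hbo_amplitude > 0
    active = frozenset(ch.name for ch in probe.long_channels
                       if is_responder and ch.roi in params.responder_channel_labels)
    reg = task_regressor(events, fs, n)
    superficial = _superficial_signal(params, t, rng)
    tau = t / t[-1] if n > 1 else t
    drift_shape = sum(c * tau**k for k, c in enumerate(params.drift_coeffs))

    od = np.empty((n, len(probe.channels), 2))
    for c, ch in enumerate(probe.channels):
        sup_frac = 1.0 if ch.is_short else _LONG_SUPERFICIAL_FRACTION
        gain = rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
        hbo = sup_frac * superficial + gain * drift_shape \
            + rng.normal(0, params.noise_sd, n)
        hbr = _HBR_SUPERFICIAL_FRACTION * sup_frac * superficial \
            - 0.3 * gain * drift_shape \
            + rng.normal(0, _HBR_NOISE_FRACTION * params.noise_sd, n)
        if ch.name in active:
            hbo = hbo + params.hbo_amplitude * reg
            hbr = hbr - params.hbr_ratio * params.hbo_amplitude * reg
        od[:, c, :] = forward_od(hbo, hbr, ch.separation, model)

    artifact_seed = int(rng.integers(0, 2**31 - 1))
    od, artifacts = inject_motion_artifacts(
        od, params.motion_spike_rate, params.motion_shift_rate,
        artifact_seed, sampling_rate=fs)

    intensity = np.exp(-od)  # I0 = 1.0 a.u. per channel
    truth = GroundTruth(is_responder, active,
                        params.hbo_amplitude if is_responder else 0.0,
                        -params.hbr_ratio * params.hbo_amplitude if is_responder else 0.0)
    rec = Recording(probe, intensity, (760.0, 850.0), fs, events,
                    subject_id=f"sim-{params.seed}",
                    meta={"ground_truth": {
                        "is_responder": truth.is_responder,
                        "active_channels": sorted(truth.active_channels),
                        "true_hbo_amplitude": truth.true_hbo_amplitude,
                        "true_hbr_amplitude": truth.true_hbr_amplitude,
                    },
                        "n_artifacts": len(artifacts)})
    rec.validate()
    return rec, truth


def cohort_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-subject seeds (< 2**31) derived from a cohort seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def simulate_cohort(n_subjects: int, responder_fraction: float,
                    base_params: SimulationParams, seed: int,
                    probe: Probe | None = None
                    ) -> list[tuple[Recording, GroundTruth]]:
    """Simulate a cohort with exactly round(n * fraction) responders.

    Responder positions within the cohort are a seeded permutation; each
    subject gets its own derived seed.
    """
    if n_subjects <= 0:
        raise ParameterError("n_subjects must be positive")
    if not 0 <= responder_fraction <= 1:
        raise ParameterError("responder_fraction must be in [0, 1]")
    n_resp = int(round(n_subjects * responder_fraction))
    order = np.random.default_rng(seed).permutation(n_subjects)
    is_resp = np.zeros(n_subjects, bool)
    is_resp[order[:n_resp]] = True
    out = []
    for i, sub_seed in enumerate(cohort_seeds(seed, n_subjects)):
        p = replace(base_params, seed=sub_seed,
                    hbo_amplitude=base_params.hbo_amplitude if is_resp[i] else 0.0)
        out.append(simulate_subject(p, probe=probe))
    return out
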