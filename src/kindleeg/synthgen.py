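"""Seeded synthetic kindling-EEG generator.

Real kindling recordings are single-channel depth-EEG traces in which
electrical stimulation evokes afterdischarges (ADs): trains of large
repetitive spikes riding on a 1/f-like background. This module emulates
those sessions with three ingredients:

* **Baseline** — 1/f^β colored noise (β ≈ 1.5) dominated by delta–theta,
  scaled to a target RMS amplitude.
* **AD segments** — a biphasic spike train (Ricker wavelets at
  ``spike_rate`` with timing jitter) superposed on band-shaped colored
  noise. The noise spectrum is piecewise flat per aggregate band
  (LFB/MFB/HFB) and its per-band energy is set, after subtracting the spike
  train's own band energies, so the segment's total band powers hit the
  calibration targets exactly per realization. The composed segment is then
  rescaled, if needed, so its 0.5 s sliding-RMS envelope never drops below
  ``ad_envelope_ratio`` × baseline RMS (a uniform rescale preserves band
  fractions).
* **Sessions** — baseline stretches interleaved with AD segments at known
  onsets, returned together with exact annotations.

Calibration targets come from group profiles (per seizure phase: target
LFB/MFB/HFB fractions, AD-duration mean/SD, event count). The defaults in
:data:`DEFAULT_PROFILES` encode the study conditions: kindle-group ISS
fractions ≈ (0.828, 0.082, 0.088), LSS ≈ (0.709, 0.132, 0.156), LSS mean
duration 12.4285 s, GSS mean 22.28 s, event counts 61/42/35 for the kindle
group, 38/13/4 for LFS-before-kindling (LFSK) and 39/14/6 for
kindling-then-LFS (KLFS).

The AD-threshold titration staircase (start 30 µA, +15 µA steps, cap
350 µA) is simulated separately via :func:`simulate_threshold_titration`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sst

from .addetect import sliding_rms
from .exceptions import CalibrationError, ConfigurationError, SchedulingError
from .records import EEGRecord, StageEvent, phase_of_stage

AGG_NAMES = ("LFB", "MFB", "HFB")
AGG_EDGES = {"LFB": (1.0, 8.0), "MFB": (8.0, 12.0), "HFB": (12.0, 40.0)}


@dataclass
class SimConfig:
    """Simulator configuration.

    Parameters
    ----------
    sampling_rate : float
        Hz. Default 1000 (10 kHz, as in acquisition hardware, is supported
        but unnecessary for a 0-40 Hz analysis: 1 kHz leaves a 12.5×
        Nyquist margin over the gamma upper edge).
    baseline_duration : float
        Seconds of baseline recorded per animal (default 7 s).
    spectral_exponent : float
        β of the 1/f^β baseline spectrum; 1.5 keeps the low-frequency band
        dominant as in resting rodent EEG.
    baseline_amplitude : float
        Baseline RMS in µV.
    ad_envelope_ratio : float
        Minimum AD envelope amplitude as a multiple of baseline RMS (> 1;
        the detection rule uses 2.5).
    ad_rms_factor : float
        Target AD RMS = ad_envelope_ratio × ad_rms_factor × baseline RMS;
        the headroom keeps envelope troughs above the detection threshold.
    envelope_margin : float
        Enforced floor of the AD 0.5 s sliding RMS, as a multiple of
        ad_envelope_ratio × baseline RMS (≥ 1).
    spike_rate : float
        AD spike rate, Hz.
    spike_power_share : float
        Upper bound on the fraction of AD power carried by the spike train
        (further capped so no band exceeds its target).
    fraction_jitter : float
        SD of per-event additive jitter applied to target band fractions
        (renormalized), modelling event-to-event spectral variability.
    inter_event_gap : float
        Baseline seconds inserted between consecutive session events.
    seed : int
        Base seed for all randomness.
    """

    sampling_rate: float = 1000.0
    baseline_duration: float = 7.0
    spectral_exponent: float = 1.5
    baseline_amplitude: float = 50.0
    ad_envelope_ratio: float = 2.5
    ad_rms_factor: float = 1.6
    envelope_margin: float = 1.15
    spike_rate: float = 5.0
    spike_power_share: float = 0.35
    fraction_jitter: float = 0.03
    inter_event_gap: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate < 2 * 40.0:
            raise ConfigurationError("sampling_rate must cover the 40 Hz gamma edge (≥ 80 Hz)")
        if self.baseline_duration <= 0 or self.inter_event_gap <= 0:
            raise ConfigurationError("durations must be positive")
        if self.ad_envelope_ratio <= 1:
            raise ConfigurationError("ad_envelope_ratio must exceed 1")
        if self.baseline_amplitude < 0:
            raise ConfigurationError("baseline_amplitude must be non-negative")
        if not 0 <= self.spike_power_share < 1:
            raise ConfigurationError("spike_power_share must lie in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class PhaseProfile:
    """Per-phase calibration: band-fraction targets, ADD distribution, count.

    ``target_fractions`` is the (LFB, MFB, HFB) triple; printed table rows
    that sum to slightly less than 1 (rounding) are renormalized, but a
    deviation beyond 0.05 is rejected as a calibration error.
    """

    target_fractions: tuple
    add_mean: float
    add_sd: float
    event_count: int

    def __post_init__(self) -> None:
        f = np.asarray(self.target_fractions, dtype=float)
        if f.size != 3 or np.any(f < 0) or np.any(f > 1):
            raise CalibrationError("target_fractions must be three values in [0, 1]")
        s = f.sum()
        if abs(s - 1.0) > 0.05:
            raise CalibrationError(f"target fractions sum to {s:.4f}, not 1")
        if abs(s - 1.0) > 1e-9:  # renormalize printed rows; idempotent otherwise
            f = f / s
        self.target_fractions = tuple(float(v) for v in f)
        if self.add_mean < 6.0:
            raise CalibrationError("add_mean below the 6 s detectability floor")
        if self.add_sd < 0 or self.event_count < 0:
            raise CalibrationError("add_sd and event_count must be non-negative")


@dataclass
class GroupProfile:
    """Calibration for one experimental group: a PhaseProfile per phase."""

    group_label: str
    phases: dict  # phase name -> PhaseProfile
    n_animals: int = 6

    def __post_init__(self) -> None:
        for phase in self.phases:
            if phase not in ("ISS", "LSS", "GSS"):
                raise CalibrationError(f"unknown phase {phase!r}")


def _profile(label, n_animals, iss, lss, gss):
    return GroupProfile(
        group_label=label,
        n_animals=n_animals,
        phases={
            "ISS": PhaseProfile(*iss),
            "LSS": PhaseProfile(*lss),
            "GSS": PhaseProfile(*gss),
        },
    )


#: Study-condition calibration. Band-fraction triples are the printed
#: per-group ISS/LSS table rows (renormalized to sum to 1); LSS/GSS mean
#: durations are the printed per-group means. ISS durations and GSS
#: fractions are not printed anywhere and use package defaults (see
#: docs/methods.md): ISS mean 8 s (SD 1.5), GSS fractions chosen to reflect
#: the described MFB/HFB elevation at generalization, attenuated in the
#: LFS-treated groups.
DEFAULT_PROFILES = {
    "Kindle": _profile(
        "Kindle", 7,
        iss=((0.828, 0.082, 0.088), 8.0, 1.5, 61),
        lss=((0.7091, 0.1323, 0.1557), 12.4285, 1.5, 42),
        gss=((0.60, 0.15, 0.25), 22.28, 2.0, 35),
    ),
    "LFSK": _profile(
        "LFSK", 6,
        iss=((0.845, 0.065, 0.081), 8.0, 1.5, 38),
        lss=((0.9124, 0.0451, 0.042), 9.373, 1.5, 13),
        gss=((0.75, 0.10, 0.15), 16.9, 2.0, 4),
    ),
    "KLFS": _profile(
        "KLFS", 6,
        iss=((0.851, 0.065, 0.074), 8.0, 1.5, 39),
        lss=((0.8825, 0.0582, 0.0592), 10.064, 1.5, 14),
        gss=((0.72, 0.11, 0.17), 17.82, 2.0, 6),
    ),
}


# ----------------------------------------------------------------- baseline


def generate_baseline(
    config: SimConfig,
    duration: float | None = None,
    rng: np.random.Generator | None = None,
) -> EEGRecord:
    """1/f^β colored-noise baseline of ``duration`` seconds (default 7 s).

    Synthesized in the frequency domain: complex-Gaussian coefficients with
    expected amplitude ∝ f^(-β/2) for 1 Hz ≤ f ≤ Nyquist, zero below 1 Hz,
    scaled to ``baseline_amplitude`` RMS. Deterministic for a given
    (config, rng state).
    """
    if duration is None:
        duration = config.baseline_duration
    if duration <= 0:
        raise ConfigurationError("baseline duration must be positive")
    rng = config.rng() if rng is None else rng
    fs = config.sampling_rate
    n = int(round(duration * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros(freqs.size)
    band = freqs >= 1.0
    shape[band] = freqs[band] ** (-config.spectral_exponent / 2.0)
    coeff = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) * shape
    x = np.fft.irfft(coeff, n=n)
    rms = np.sqrt(np.mean(x * x))
    if rms > 0 and config.baseline_amplitude > 0:
        x *= config.baseline_amplitude / rms
    else:
        x = np.zeros(n)
    return EEGRecord(samples=x, sampling_rate=fs, label="baseline")


# --------------------------------------------------------------- AD segment


def _ricker(fs: float, sigma: float = 0.04) -> np.ndarray:
    """Biphasic sharp transient (Ricker wavelet), unit peak amplitude."""
    half = int(round(4 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    u = (t / sigma) ** 2
    return (1.0 - u) * np.exp(-u / 2.0)


def _band_powers_fft(coeff: np.ndarray, freqs: np.ndarray, n: int) -> dict:
    """Mean-square power per aggregate band from one-sided FFT coefficients."""
    out = {}
    for name, (lo, hi) in AGG_EDGES.items():
        mask = (freqs >= lo) & (freqs < hi)
        # one-sided: interior bins count twice in the mean square
        out[name] = 2.0 * np.sum(np.abs(coeff[mask]) ** 2) / n**2
    return out


def generate_ad_segment(
    profile_entry: PhaseProfile,
    duration: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    jitter_fractions: bool = True,
) -> EEGRecord:
    """One AD segment of ``duration`` seconds calibrated to a phase profile.

    The spike train is synthesized first and its per-band powers measured
    from its FFT; the colored-noise component then receives exactly the
    remaining per-band power, so the composed segment's band powers match
    the (optionally jittered) targets per realization. The spike amplitude
    is capped so no band's spike power exceeds its target. Finally the
    segment is uniformly rescaled so that every 0.5 s sliding-RMS window
    stays ≥ envelope_margin × ad_envelope_ratio × baseline RMS.
    """
    if duration <= 0:
        raise ConfigurationError("AD duration must be positive")
    rng = config.rng() if rng is None else rng
    fs = config.sampling_rate
    n = int(round(duration * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    targets = np.asarray(profile_entry.target_fractions, dtype=float)
    if jitter_fractions and config.fraction_jitter > 0:
        targets = targets + rng.normal(0.0, config.fraction_jitter, size=3)
        targets = np.clip(targets, 0.0, None)
        if targets.sum() <= 0:
            targets = np.asarray(profile_entry.target_fractions, dtype=float)
        targets = targets / targets.sum()
    target_power = dict(zip(AGG_NAMES, targets))

    total_rms = config.ad_envelope_ratio * config.ad_rms_factor * config.baseline_amplitude
    p_total = total_rms**2

    # --- spike train
    spikes = np.zeros(n)
    if config.spike_rate > 0 and config.spike_power_share > 0:
        wav = _ricker(fs)
        period = 1.0 / config.spike_rate
        times = np.arange(0.5 * period, duration - 0.5 * period, period)
        times = times + rng.normal(0.0, 0.1 * period, size=times.size)
        amps = rng.uniform(0.8, 1.2, size=times.size)
        half = (wav.size - 1) // 2
        for t, a in zip(times, amps):
            c = int(round(t * fs))
            i0, i1 = c - half, c + half + 1
            w0, w1 = max(0, -i0), wav.size - max(0, i1 - n)
            i0, i1 = max(i0, 0), min(i1, n)
            if i1 > i0:
                spikes[i0:i1] += a * wav[w0:w1]
        s_coeff = np.fft.rfft(spikes)
        s_band = _band_powers_fft(s_coeff, freqs, n)
        s_tot = sum(s_band.values())
        if s_tot > 0:
            scale2 = config.spike_power_share * p_total / s_tot
            for name in AGG_NAMES:
                if s_band[name] > 0:
                    cap = 0.95 * target_power[name] * p_total / s_band[name]
                    scale2 = min(scale2, cap)
            scale2 = max(scale2, 0.0)
            spikes *= np.sqrt(scale2)
            s_band = {k: v * scale2 for k, v in s_band.items()}
        else:
            s_band = {k: 0.0 for k in AGG_NAMES}
    else:
        s_band = {k: 0.0 for k in AGG_NAMES}

    # --- band-shaped noise filling the per-band power deficit.
    # Within each aggregate band the expected density slopes as 1/f, as in
    # real EEG. Each band's noise is synthesized once with unit band power
    # so its gain can be re-tuned below.
    unit_noise: dict = {}
    for name in AGG_NAMES:
        lo, hi = AGG_EDGES[name]
        mask = (freqs >= lo) & (freqs < hi)
        m = int(np.count_nonzero(mask))
        if m == 0:
            continue
        z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
        z = z * freqs[mask] ** -0.5
        # cosine-taper the top 0.75 Hz of the band so the Hann/Welch main
        # lobe does not smear band-edge density into the neighbour above
        taper_width = min(0.75, 0.25 * (hi - lo))
        ramp = np.clip((hi - freqs[mask]) / taper_width, 0.0, 1.0)
        z = z * np.sin(0.5 * np.pi * ramp)
        power = 2.0 * np.sum(np.abs(z) ** 2) / n**2
        coeff = np.zeros(freqs.size, dtype=complex)
        coeff[mask] = z / np.sqrt(power)
        unit_noise[name] = np.fft.irfft(coeff, n=n)

    # Closed-loop calibration: the finite Hann/Welch analysis smears power
    # across band edges (its main lobe is ~2/segment_length Hz wide), so
    # exact synthesis band powers do not measure back exactly. Iterate the
    # per-band noise gains until the fractions recovered by the default
    # spectral analysis match the targets.
    from .spectral import DEFAULT_BANDS, band_fractions as _bf, welch_psd as _welch

    band_power = {
        name: max(target_power[name] * p_total - s_band[name], 0.0) for name in AGG_NAMES
    }
    x = spikes.copy()
    for it in range(4):
        x = spikes.copy()
        for name, u in unit_noise.items():
            if band_power[name] > 0:
                x = x + np.sqrt(band_power[name]) * u
        if n < int(round(2.0 * fs)):
            break  # too short for the default analysis; keep exact synthesis
        measured = _bf(_welch(EEGRecord(samples=x, sampling_rate=fs)), DEFAULT_BANDS).fraction
        errs = [abs(measured[name] - target_power[name]) for name in AGG_NAMES]
        if max(errs) < 0.002 or it == 3:
            break
        for name in AGG_NAMES:
            if measured[name] <= 0:
                continue
            gain = np.clip(target_power[name] / measured[name], 0.25, 4.0)
            total_b = (s_band[name] + band_power[name]) * gain
            band_power[name] = max(total_b - s_band[name], 0.0)

    # --- envelope floor (uniform rescale preserves band fractions)
    if config.baseline_amplitude > 0 and n >= int(round(0.5 * fs)):
        _, env = sliding_rms(x, fs, window=0.5, overlap=0.5)
        floor = config.envelope_margin * config.ad_envelope_ratio * config.baseline_amplitude
        if env.min() < floor and env.min() > 0:
            x *= floor / env.min()
    return EEGRecord(samples=x, sampling_rate=fs, label="ad")


# ------------------------------------------------------------------ session


@dataclass
class ScheduledEvent:
    """One planned AD in a session.

    ``duration`` and ``onset`` may be left None to be drawn/laid out by the
    simulator (durations from a truncated normal at the phase profile's
    mean/SD, lower bound 6 s; onsets sequential with ``inter_event_gap``
    baseline in between).
    """

    animal_id: str
    racine_stage: int
    day: int = 1
    onset: float | None = None
    duration: float | None = None

    @property
    def phase(self) -> str:
        return phase_of_stage(self.racine_stage)


def default_schedule(profile: GroupProfile) -> list[ScheduledEvent]:
    """Round-robin assignment of the profile's event counts to its animals.

    ISS events alternate Racine stages 1/2 and GSS events stages 4/5; days
    advance every 12 events (stimulations were delivered 12 per day).
    """
    stage_cycle = {"ISS": (1, 2), "LSS": (3,), "GSS": (4, 5)}
    events: list[ScheduledEvent] = []
    k = 0
    for phase in ("ISS", "LSS", "GSS"):
        entry = profile.phases.get(phase)
        if entry is None:
            continue
        for i in range(entry.event_count):
            events.append(
                ScheduledEvent(
                    animal_id=f"{profile.group_label}-{i % profile.n_animals + 1:02d}",
                    racine_stage=stage_cycle[phase][i % len(stage_cycle[phase])],
                    day=k // 12 + 1,
                )
            )
            k += 1
    return events


# Durations are truncated half a second above the 6 s detection rule: the
# detector's boundary localization error is bounded by ~0.35 s, so an AD
# drawn at the floor still measures above the minimum-duration criterion.
DURATION_FLOOR = 6.5


def _draw_duration(entry: PhaseProfile, rng: np.random.Generator) -> float:
    if entry.add_sd == 0:
        return max(entry.add_mean, DURATION_FLOOR)
    a = (DURATION_FLOOR - entry.add_mean) / entry.add_sd
    return float(
        sst.truncnorm.rvs(a, np.inf, loc=entry.add_mean, scale=entry.add_sd, random_state=rng)
    )


def simulate_session(
    profile: GroupProfile,
    schedule: Sequence[ScheduledEvent] | None = None,
    config: SimConfig | None = None,
    seed: int | None = None,
) -> tuple[EEGRecord, list[StageEvent]]:
    """Simulate one group session: continuous record + exact annotations.

    The record is an initial ``baseline_duration`` baseline stretch followed
    by AD segments separated by ``inter_event_gap`` baseline. Annotations
    match the embedded segments exactly. Identical (profile, schedule,
    config, seed) give bitwise-identical output.
    """
    config = SimConfig() if config is None else config
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = default_schedule(profile)
    for ev in schedule:
        if ev.phase not in profile.phases:
            raise SchedulingError(f"schedule contains phase {ev.phase} absent from profile")
    explicit = [ev for ev in schedule if ev.onset is not None]
    if explicit:
        ordered = sorted(explicit, key=lambda e: e.onset)
        for a, b in zip(ordered[:-1], ordered[1:]):
            da = a.duration if a.duration is not None else profile.phases[a.phase].add_mean
            if b.onset < a.onset + da:
                raise SchedulingError("scheduled events overlap")

    fs = config.sampling_rate
    chunks: list[np.ndarray] = []
    annotations: list[StageEvent] = []
    t = 0.0

    lead = generate_baseline(config, duration=config.baseline_duration, rng=rng)
    chunks.append(lead.samples)
    t += lead.duration

    for ev in schedule:
        entry = profile.phases[ev.phase]
        gap = generate_baseline(config, duration=config.inter_event_gap, rng=rng)
        chunks.append(gap.samples)
        t += gap.duration
        dur = ev.duration if ev.duration is not None else _draw_duration(entry, rng)
        seg = generate_ad_segment(entry, dur, config, rng=rng)
        annotations.append(
            StageEvent(
                onset_s=t,
                duration_s=seg.duration,
                racine_stage=ev.racine_stage,
                animal_id=ev.animal_id,
                group=profile.group_label,
                day=ev.day,
            )
        )
        chunks.append(seg.samples)
        t += seg.duration

    tail = generate_baseline(config, duration=config.inter_event_gap, rng=rng)
    chunks.append(tail.samples)
    record = EEGRecord(
        samples=np.concatenate(chunks) if chunks else np.zeros(0),
        sampling_rate=fs,
        label=f"session-{profile.group_label}",
    )
    return record, annotations


# ---------------------------------------------------------------- titration


@dataclass
class ResponseCurve:
    """Probability of evoking an AD as a function of stimulus intensity (µA).

    With only ``true_threshold`` set, the response is a deterministic step
    (AD iff intensity ≥ threshold); ``true_threshold=None`` models a
    non-responder. A custom monotone ``prob`` function may be supplied.
    """

    true_threshold: float | None = None
    prob: Callable[[float], float] | None = None

    def probability(self, intensity: float) -> float:
        if self.prob is not None:
            p = float(self.prob(intensity))
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("response probability outside [0, 1]")
            return p
        if self.true_threshold is None:
            return 0.0
        return 1.0 if intensity >= self.true_threshold else 0.0


@dataclass
class TitrationResult:
    """Outcome of a threshold titration staircase."""

    threshold_intensity: float | None
    steps_taken: int
    excluded: bool


def simulate_threshold_titration(
    curve: ResponseCurve,
    start: float = 30.0,
    step: float = 15.0,
    maximum: float = 350.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TitrationResult:
    """Ascending staircase: start µA, +step increments, capped at maximum.

    At each intensity a Bernoulli draw from the response curve decides
    whether an AD was evoked; the first responding intensity is the
    threshold. Animals with no AD by the maximum intensity are excluded.
    """
    if step <= 0:
        raise ConfigurationError("step must be positive")
    if start > maximum:
        raise ConfigurationError("start must not exceed maximum")
    if rng is None:
        rng = np.random.default_rng(seed)
    intensity = start
    steps = 0
    while intensity <= maximum + 1e-9:
        steps += 1
        if rng.random() < curve.probability(intensity):
            return TitrationResult(threshold_intensity=intensity, steps_taken=steps, excluded=False)
        intensity += step
    return TitrationResult(threshold_intensity=None, steps_taken=steps, excluded=True)
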