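"""Synthetic inputs with known ground truth for every pipeline stage.

Emulated structure: juvenile song bouts of consecutive syllables on the box
microphone; female calls on both channels, louder on the backpack, whose
in-song rate can grow linearly with age; intracellular trial sets with a
shared stimulus-locked subthreshold component plus private colored noise and
superimposed spikes; stereotyped singing motifs with optional call-evoked
deflections or extra spikes; and populations of sorted units in the two
spontaneous-rate classes with configurable quality metrics.

Acoustics are deliberately minimal — band-limited noise bursts (syllables)
and harmonic stacks (calls) with 5 ms cosine ramps — because the envelope
segmenter only sees amplitude, not spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, lfilter, sosfiltfilt

from .io import AudioClip, EventTable, VocalEvent, seconds_to_samples
from .intracellular import IntracellularTrialSet
from .interaction import SessionSummary
from .extracellular import UnitRecord
from .segment import SongBout, assemble_song_bouts

# ---------------------------------------------------------------------------
# tutor playback

TUTOR_SYLLABLE_A_S = 0.185
TUTOR_SYLLABLE_B_S = 0.155
TUTOR_GAP_AFTER_A_S = 0.119
TUTOR_GAP_AFTER_B_S = 0.124
TUTOR_PITCH_A_HZ = 2456.6
TUTOR_PITCH_B_HZ = 1165.4


def _cosine_ramps(n: int, ramp_n: int) -> np.ndarray:
    env = np.ones(n)
    r = min(ramp_n, n // 2)
    if r > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = ramp
        env[-r:] = ramp[::-1]
    return env


def _tone_complex(dur_s: float, f0: float, sample_rate: int, amp: float = 0.3) -> np.ndarray:
    t = np.arange(int(round(dur_s * sample_rate))) / sample_rate
    w = np.zeros_like(t)
    for k, a in enumerate((1.0, 0.5, 0.25), start=1):
        w += a * np.sin(2 * np.pi * k * f0 * t)
    w *= amp / np.max(np.abs(w))
    return w * _cosine_ramps(len(w), int(0.005 * sample_rate))


def render_tutor_audio(
    sample_rate: int = 44100, noise_floor: float = 1e-4, seed: int = 0
) -> tuple[AudioClip, EventTable]:
    """Render the synthesized ABAB tutor motif and its ground-truth events.

    Syllable A: 185 ms tone complex near 2456.6 Hz; syllable B: 155 ms near
    1165.4 Hz; internal gaps 119 ms (after A) and 124 ms (after B), giving a
    1.042 s motif of four syllables.
    """
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz")
    rng = np.random.default_rng(seed)
    plan = [
        ("A", TUTOR_SYLLABLE_A_S, TUTOR_PITCH_A_HZ, TUTOR_GAP_AFTER_A_S),
        ("B", TUTOR_SYLLABLE_B_S, TUTOR_PITCH_B_HZ, TUTOR_GAP_AFTER_B_S),
        ("A", TUTOR_SYLLABLE_A_S, TUTOR_PITCH_A_HZ, TUTOR_GAP_AFTER_A_S),
        ("B", TUTOR_SYLLABLE_B_S, TUTOR_PITCH_B_HZ, 0.0),
    ]
    total = sum(d + g for _, d, _, g in plan)
    n = int(round(total * sample_rate))
    samples = rng.normal(0.0, noise_floor, n)
    events = []
    t = 0.0
    for label, dur, f0, gap in plan:
        i0, _ = seconds_to_samples(t, t + dur, sample_rate)
        w = _tone_complex(dur, f0, sample_rate)
        samples[i0: i0 + len(w)] += w
        events.append(
            VocalEvent(
                kind="syllable", onset_s=t, offset_s=t + dur, channel_tag="playback", label=label
            )
        )
        t += dur + gap
    clip = AudioClip(samples=samples, sample_rate=sample_rate, channel_tag="playback")
    return clip, EventTable(events=events, bird_id="tutor", recording_id="tutor_motif")


# ---------------------------------------------------------------------------
# behavioral sessions


@dataclass
class SessionSimConfig:
    """Conditions of one juvenile/female recording session.

    The in-song female call rate follows a linear age trend,
    ``max(0, call_base_rate_hz + call_age_slope * (age_dph - call_age0_dph))``.
    """

    age_dph: int = 60
    bout_rate_per_min: float = 4.0
    bout_dur_mean_s: float = 1.5
    bout_dur_sd_s: float = 0.4
    syllable_dur_mean_s: float = 0.090
    syllable_dur_sd_s: float = 0.020
    gap_mean_s: float = 0.080
    gap_sd_s: float = 0.020
    call_base_rate_hz: float = 0.5
    call_age_slope_hz_per_day: float = 0.0
    call_age0_dph: int = 60
    call_rate_out_song_hz: float = 0.02
    call_dur_s: float = 0.090
    session_dur_s: float = 120.0
    noise_floor: float = 0.005
    syllable_rms: float = 0.25
    call_rms: float = 0.30
    backpack_attenuation_db: float = -20.0
    sample_rate: int = 40000
    seed: int = 0

    def call_rate_in_song_hz(self, age_dph: int | None = None) -> float:
        age = self.age_dph if age_dph is None else age_dph
        return max(
            0.0,
            self.call_base_rate_hz
            + self.call_age_slope_hz_per_day * (age - self.call_age0_dph),
        )


def _truncated_normal(rng, mean, sd, lo, hi=np.inf) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi if np.isfinite(hi) else mean))


def simulate_session_events(cfg: SessionSimConfig, rng: np.random.Generator | None = None) -> EventTable:
    """Generate the ground-truth event table of one session (no audio).

    Juvenile syllables (box channel) arrive in bouts placed by a Poisson
    process; female call onsets follow an inhomogeneous Poisson process with
    the in-song rate inside bout windows and the out-of-song rate elsewhere
    (backpack channel); bout windows are recorded as song_bout events.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    if cfg.session_dur_s <= 0:
        raise ValueError("session_dur_s must be positive")
    events: list[VocalEvent] = []
    bout_windows: list[tuple[float, float]] = []

    # song bouts: Poisson onsets, non-overlapping with >= 0.5 s separation
    # so the assembly rule (>= 350 ms silence) keeps them distinct
    rate = cfg.bout_rate_per_min / 60.0
    t = 0.0
    while rate > 0:
        t += rng.exponential(1.0 / rate)
        if t >= cfg.session_dur_s:
            break
        span = _truncated_normal(rng, cfg.bout_dur_mean_s, cfg.bout_dur_sd_s, 0.5)
        if bout_windows and t < bout_windows[-1][1] + 0.5:
            t = bout_windows[-1][1] + 0.5
            if t >= cfg.session_dur_s:
                break
        end = min(t + span, cfg.session_dur_s)
        # fill the bout with syllables
        s = t
        sylls: list[tuple[float, float]] = []
        while True:
            dur = _truncated_normal(rng, cfg.syllable_dur_mean_s, cfg.syllable_dur_sd_s, 0.02)
            if s + dur > end:
                break
            sylls.append((s, s + dur))
            gap = _truncated_normal(rng, cfg.gap_mean_s, cfg.gap_sd_s, 0.02, 0.30)
            s = s + dur + gap
        if not sylls:
            continue
        span_on, span_off = sylls[0][0], sylls[-1][1]
        for a, b in sylls:
            events.append(VocalEvent(kind="syllable", onset_s=a, offset_s=b, channel_tag="box"))
        if span_off - span_on >= 0.400:
            events.append(
                VocalEvent(kind="song_bout", onset_s=span_on, offset_s=span_off, channel_tag="box")
            )
            bout_windows.append((span_on, span_off))
        t = span_off

    # female calls: in-song rate inside bout windows, out-of-song elsewhere
    lam_in = cfg.call_rate_in_song_hz()
    for a, b in bout_windows:
        if lam_in <= 0:
            continue
        k = rng.poisson(lam_in * (b - a))
        for onset in np.sort(rng.uniform(a, b, size=k)):
            events.append(
                VocalEvent(
                    kind="call",
                    onset_s=float(onset),
                    offset_s=float(onset) + cfg.call_dur_s,
                    channel_tag="backpack",
                )
            )
    if cfg.call_rate_out_song_hz > 0:
        k = rng.poisson(cfg.call_rate_out_song_hz * cfg.session_dur_s)
        for onset in np.sort(rng.uniform(0, cfg.session_dur_s, size=k)):
            if any(a <= onset < b for a, b in bout_windows):
                continue
            events.append(
                VocalEvent(
                    kind="call",
                    onset_s=float(onset),
                    offset_s=float(onset) + cfg.call_dur_s,
                    channel_tag="backpack",
                )
            )
    return EventTable(
        events=events,
        bird_id=f"sim_bird_{cfg.seed}",
        female_id=f"sim_female_{cfg.seed}",
        age_dph=cfg.age_dph,
        recording_id=f"sim_session_{cfg.seed}",
    )


def _noise_burst(dur_s: float, sample_rate: int, rms: float, rng) -> np.ndarray:
    n = int(round(dur_s * sample_rate))
    w = rng.normal(0.0, 1.0, n)
    sos = butter(4, [1000, min(8000, sample_rate / 2 - 1)], btype="band", fs=sample_rate, output="sos")
    w = sosfiltfilt(sos, w)
    w *= rms / max(w.std(), 1e-12)
    return w * _cosine_ramps(n, int(0.005 * sample_rate))


def _harmonic_stack(dur_s: float, sample_rate: int, rms: float, f0: float = 600.0) -> np.ndarray:
    t = np.arange(int(round(dur_s * sample_rate))) / sample_rate
    w = sum(np.sin(2 * np.pi * k * f0 * t) / k for k in range(1, 6))
    w = np.asarray(w)
    w *= rms / max(w.std(), 1e-12)
    return w * _cosine_ramps(len(w), int(0.005 * sample_rate))


def simulate_session(
    cfg: SessionSimConfig,
) -> tuple[AudioClip, AudioClip, EventTable]:
    """Render one session as (box audio, backpack audio, ground truth).

    Juvenile syllables appear on the box channel only at full level (and at
    -20 dB on the backpack, emulating its bias toward the wearer); female
    calls appear on both channels, louder on the backpack.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_session_events(cfg, rng)
    n = int(round(cfg.session_dur_s * cfg.sample_rate))
    box = rng.normal(0.0, cfg.noise_floor, n)
    backpack = rng.normal(0.0, cfg.noise_floor, n)
    atten = 10.0 ** (cfg.backpack_attenuation_db / 20.0)
    for ev in truth.events:
        i0, _ = seconds_to_samples(ev.onset_s, ev.offset_s, cfg.sample_rate)
        if ev.kind == "syllable":
            w = _noise_burst(ev.duration_s, cfg.sample_rate, cfg.syllable_rms, rng)
            box[i0: i0 + len(w)] += w[: max(0, n - i0)]
            backpack[i0: i0 + len(w)] += atten * w[: max(0, n - i0)]
        elif ev.kind == "call":
            w = _harmonic_stack(ev.duration_s, cfg.sample_rate, cfg.call_rms)
            m = min(len(w), max(0, n - i0))
            backpack[i0: i0 + m] += w[:m]
            box[i0: i0 + m] += 0.5 * w[:m]
    return (
        AudioClip(box, cfg.sample_rate, "box"),
        AudioClip(backpack, cfg.sample_rate, "backpack"),
        truth,
    )


def true_bouts(truth: EventTable) -> list[SongBout]:
    """Ground-truth song bouts of a simulated session as SongBout objects."""
    sylls = truth.of_kind("syllable")
    return assemble_song_bouts(sylls)


def simulate_development(
    template: SessionSimConfig, ages: list[int]
) -> tuple[list[tuple[EventTable, SessionSummary]], float]:
    """One session per age with the configured linear in-song call-rate trend.

    Returns the per-age (ground-truth events, ground-truth summary) pairs and
    the true slope in calls/s per day.  Ages must be strictly increasing.
    """
    if any(b <= a for a, b in zip(ages, ages[1:])):
        raise ValueError("ages must be strictly increasing")
    out = []
    for i, age in enumerate(ages):
        cfg = replace(template, age_dph=age, seed=template.seed + 1000 * i)
        truth = simulate_session_events(cfg)
        bouts = true_bouts(truth)
        calls = truth.of_kind("call")
        total = sum(b.duration_s for b in bouts)
        n_in = 0
        for c in calls.events:
            if any(b.onset_s <= c.onset_s < b.offset_s for b in bouts):
                n_in += 1
        out.append(
            (
                truth,
                SessionSummary(
                    bird_id=truth.bird_id,
                    age_dph=age,
                    n_bouts=len(bouts),
                    total_song_dur_s=total,
                    n_calls_in_song=n_in,
                    call_ratio=(n_in / total) if total > 0 else None,
                    n_songs_produced=len(bouts),
                ),
            )
        )
    return out, template.call_age_slope_hz_per_day


# ---------------------------------------------------------------------------
# intracellular trial sets


@dataclass
class TrialSimConfig:
    """Conditions of a playback trial set.

    ``shared_fraction`` (rho) is the fraction of subthreshold variance inside
    the stimulus window carried by a stimulus-locked component identical
    across trials, so the expected zero-lag pairwise correlation equals rho.
    Locked spike counts are Poisson(``lambda_locked``) per trial at template
    latencies jittered by ``jitter_sd_s``.  Spike height is >= 30 mV per the
    sharp-recording inclusion rule, so 15 mV threshold detection is exhaustive.
    """

    n_trials: int = 15
    trial_dur_s: float = 0.6
    call_onset_s: float = 0.30
    call_offset_s: float = 0.45
    baseline_mV: float = -70.0
    noise_sd_mV: float = 2.0
    noise_tau_s: float = 0.010
    shared_fraction: float = 0.0
    shared_smooth_s: float = 0.005
    deflection_mV: float = 0.0
    lambda_locked: float = 0.0
    n_locked_latencies: int = 3
    locked_span_s: float = 0.030
    jitter_sd_s: float = 0.002
    background_rate_hz: float = 0.0
    spike_height_mV: float = 45.0
    spike_width_s: float = 0.002
    sample_rate: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must lie in [0, 1]")
        if self.spike_height_mV < 30.0:
            raise ValueError("spike height must be >= 30 mV (inclusion rule)")


@dataclass
class TrialGroundTruth:
    spike_times: list[np.ndarray]
    subthreshold_mV: np.ndarray
    shared_waveform: np.ndarray


def _ou_noise(rng, n, dt, tau, sd) -> np.ndarray:
    """Exponentially correlated (Ornstein-Uhlenbeck) noise at stationary sd,
    realized as the equivalent AR(1) recursion."""
    a = np.exp(-dt / tau)
    b = sd * np.sqrt(1 - a * a)
    eps = b * rng.normal(0.0, 1.0, n)
    eps[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -a], eps)


def _spike_waveform(height, width_s, sample_rate) -> np.ndarray:
    sd = width_s / 4.0
    half = int(round(3 * sd * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    return height * np.exp(-(t**2) / (2 * sd**2))


def simulate_intracellular_trialset(
    cfg: TrialSimConfig,
) -> tuple[IntracellularTrialSet, TrialGroundTruth]:
    """Generate trials = baseline + shared stimulus-locked component +
    private colored noise + spikes, plus the spike-free ground truth."""
    rng = np.random.default_rng(cfg.seed)
    sr = cfg.sample_rate
    n = int(round(cfg.trial_dur_s * sr))
    i0, i1 = seconds_to_samples(cfg.call_onset_s, cfg.call_offset_s, sr)
    nw = i1 - i0
    # one fixed smooth waveform per seed, exactly unit sample SD in window
    shared = gaussian_filter1d(rng.normal(0, 1, nw), cfg.shared_smooth_s * sr)
    shared = (shared - shared.mean()) / max(shared.std(), 1e-12)
    rho = cfg.shared_fraction
    sd_priv = cfg.noise_sd_mV * np.sqrt(1 - rho)
    amp_shared = cfg.noise_sd_mV * np.sqrt(rho)

    # an evoked response is a short latency-concentrated burst: template
    # latencies fall within one locked_span_s-long span inside the window
    span = min(cfg.locked_span_s, cfg.call_offset_s - cfg.call_onset_s - 0.02)
    burst_start = rng.uniform(
        cfg.call_onset_s + 0.01, cfg.call_offset_s - 0.01 - span
    )
    template_lat = np.sort(rng.uniform(burst_start, burst_start + span, cfg.n_locked_latencies))
    wave = _spike_waveform(cfg.spike_height_mV, cfg.spike_width_s, sr)
    half = len(wave) // 2

    vm = np.empty((cfg.n_trials, n))
    sub = np.empty((cfg.n_trials, n))
    spikes: list[np.ndarray] = []
    for k in range(cfg.n_trials):
        noise = _ou_noise(rng, n, 1 / sr, cfg.noise_tau_s, sd_priv)
        if rho > 0 and sd_priv > 0:
            # rho is defined on in-window *sample* variances: rescale the
            # private noise so its sample SD inside the window is exactly
            # sd_priv, matching the exactly-normalized shared component
            w_sd = noise[i0:i1].std()
            if w_sd > 0:
                noise *= sd_priv / w_sd
        trace = cfg.baseline_mV + noise
        trace[i0:i1] += amp_shared * shared + cfg.deflection_mV
        sub[k] = trace
        tr = trace.copy()
        times = []
        if cfg.lambda_locked > 0:
            for _ in range(rng.poisson(cfg.lambda_locked)):
                t0 = rng.choice(template_lat) + rng.normal(0, cfg.jitter_sd_s)
                times.append(t0)
        if cfg.background_rate_hz > 0:
            k_bg = rng.poisson(cfg.background_rate_hz * cfg.trial_dur_s)
            times.extend(rng.uniform(0, cfg.trial_dur_s, k_bg))
        # enforce a 2 ms separation so detection count matches ground truth
        times = sorted(t for t in times if 0.005 < t < cfg.trial_dur_s - 0.005)
        kept = []
        for t0 in times:
            if not kept or t0 - kept[-1] >= 0.002:
                kept.append(t0)
        for t0 in kept:
            c = int(round(t0 * sr))
            a, b = max(0, c - half), min(n, c + half + 1)
            tr[a:b] += wave[half - (c - a): half + (b - c)]
        vm[k] = tr
        spikes.append(np.array(kept))
    ts = IntracellularTrialSet(
        vm_mV=vm,
        sample_rate=sr,
        window=(cfg.call_onset_s, cfg.call_offset_s),
        kind="playback_call",
        baseline_mV=cfg.baseline_mV,
        cell_id=f"sim_cell_{cfg.seed}",
        bird_id=f"sim_bird_{cfg.seed}",
    )
    return ts, TrialGroundTruth(spike_times=spikes, subthreshold_mV=sub, shared_waveform=shared)


# ---------------------------------------------------------------------------
# singing perturbations


@dataclass
class PerturbationSimConfig:
    """Stereotyped singing motifs with call perturbations on a subset.

    Unperturbed renditions share one smooth membrane-potential motif pattern
    and fixed template spike latencies (plus private noise); perturbed
    renditions add a boxcar deflection and/or ``extra_spikes`` extra spikes
    inside the call window + pad.
    """

    n_renditions: int = 24
    perturbed: tuple[int, ...] = tuple(range(0, 24, 4))
    motif_dur_s: float = 1.0
    call_onset_s: float = 0.40
    call_offset_s: float = 0.50
    pad_s: float = 0.050
    baseline_mV: float = -70.0
    noise_sd_mV: float = 1.0
    noise_tau_s: float = 0.010
    pattern_amp_mV: float = 5.0
    template_spike_latencies: tuple[float, ...] = (0.15, 0.70, 0.85)
    deflection_mV: float = 0.0
    extra_spikes: int = 0
    spike_height_mV: float = 45.0
    spike_width_s: float = 0.002
    sample_rate: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(i < 0 or i >= self.n_renditions for i in self.perturbed):
            raise ValueError("perturbed indices must lie within renditions")


def simulate_singing_perturbation(
    cfg: PerturbationSimConfig,
) -> tuple[IntracellularTrialSet, TrialGroundTruth]:
    rng = np.random.default_rng(cfg.seed)
    sr = cfg.sample_rate
    n = int(round(cfg.motif_dur_s * sr))
    pattern = gaussian_filter1d(rng.normal(0, 1, n), 0.02 * sr)
    pattern *= cfg.pattern_amp_mV / max(pattern.std(), 1e-12)
    # the stereotyped motif pattern is subthreshold by construction: keep it
    # clear of baseline + 15 mV so only template/extra spikes cross threshold
    pattern = np.clip(pattern, -10.0, 10.0)
    i0, i1 = seconds_to_samples(cfg.call_onset_s, min(cfg.call_offset_s + cfg.pad_s, cfg.motif_dur_s), sr)
    wave = _spike_waveform(cfg.spike_height_mV, cfg.spike_width_s, sr)
    half = len(wave) // 2
    # extra spike latencies are fixed per config so a +k effect is exact
    extra_lat = rng.uniform(cfg.call_onset_s + 0.005, cfg.call_offset_s + cfg.pad_s - 0.005,
                            cfg.extra_spikes) if cfg.extra_spikes else np.array([])

    vm = np.empty((cfg.n_renditions, n))
    sub = np.empty((cfg.n_renditions, n))
    spikes: list[np.ndarray] = []
    for k in range(cfg.n_renditions):
        trace = cfg.baseline_mV + pattern + _ou_noise(rng, n, 1 / sr, cfg.noise_tau_s, cfg.noise_sd_mV)
        times = list(cfg.template_spike_latencies)
        if k in cfg.perturbed:
            trace[i0:i1] += cfg.deflection_mV
            times.extend(extra_lat)
        sub[k] = trace
        tr = trace.copy()
        for t0 in sorted(times):
            c = int(round(t0 * sr))
            a, b = max(0, c - half), min(n, c + half + 1)
            tr[a:b] += wave[half - (c - a): half + (b - c)]
        vm[k] = tr
        spikes.append(np.array(sorted(times)))
    ts = IntracellularTrialSet(
        vm_mV=vm,
        sample_rate=sr,
        window=(cfg.call_onset_s, cfg.call_offset_s),
        kind="call",
        baseline_mV=cfg.baseline_mV,
        cell_id=f"sim_singing_cell_{cfg.seed}",
        bird_id=f"sim_bird_{cfg.seed}",
        perturbed=tuple(cfg.perturbed),
    )
    return ts, TrialGroundTruth(spike_times=spikes, subthreshold_mV=sub, shared_waveform=pattern)


# ---------------------------------------------------------------------------
# extracellular populations


@dataclass
class PopulationSimConfig:
    """A sorted-unit population under a periodic playback schedule.

    Projection-class units are drawn with spontaneous rate <= 2 Hz,
    interneuron-class above; ``response_gain`` scales the rate inside the
    call + 50 ms window, and ``locked_rate_hz`` adds stimulus-locked spikes
    at jittered template latencies.
    """

    n_units: int = 20
    projection_fraction: float = 0.8
    projection_rate_range_hz: tuple[float, float] = (0.3, 1.8)
    interneuron_rate_range_hz: tuple[float, float] = (3.0, 12.0)
    response_gain: float = 1.0
    locked_rate_hz: float = 0.0
    jitter_sd_s: float = 0.003
    n_trials: int = 60
    period_s: float = 1.5
    stim_dur_s: float = 0.150
    pre_s: float = 0.5
    pad_s: float = 0.050
    qc_failures: tuple[tuple[int, str], ...] = ()
    seed: int = 0


def make_stimulus_schedule(
    n_trials: int = 60, period_s: float = 1.5, stim_dur_s: float = 0.150, start_s: float = 0.5
) -> list[VocalEvent]:
    """Playback schedule: one call every ``period_s`` for ``n_trials`` trials
    (onsets span ``(n_trials - 1) * period_s`` seconds plus the call)."""
    return [
        VocalEvent(
            kind="playback_call",
            onset_s=start_s + k * period_s,
            offset_s=start_s + k * period_s + stim_dur_s,
            channel_tag="playback",
        )
        for k in range(n_trials)
    ]


def simulate_population_units(
    cfg: PopulationSimConfig,
) -> tuple[list[UnitRecord], list[VocalEvent], float]:
    """Generate (units, stimulus schedule, session duration).

    QC metrics are generated in the passing range; entries of
    ``qc_failures`` force one named metric of one unit across its failing
    threshold.
    """
    rng = np.random.default_rng(cfg.seed)
    schedule = make_stimulus_schedule(cfg.n_trials, cfg.period_s, cfg.stim_dur_s, cfg.pre_s)
    session_dur = schedule[-1].offset_s + cfg.pad_s + cfg.pre_s
    fail_map: dict[int, str] = {i: m for i, m in cfg.qc_failures}
    units: list[UnitRecord] = []
    n_proj = int(round(cfg.projection_fraction * cfg.n_units))
    win = cfg.stim_dur_s + cfg.pad_s
    for i in range(cfg.n_units):
        is_proj = i < n_proj
        lo, hi = cfg.projection_rate_range_hz if is_proj else cfg.interneuron_rate_range_hz
        rate = rng.uniform(lo, hi)
        # locked latencies are fixed per unit so spikes align across trials
        template_lat = rng.uniform(0.005, win - 0.005, 3)
        spikes = list(rng.uniform(0, session_dur, rng.poisson(rate * session_dur)))
        for ev in schedule:
            extra = rate * (cfg.response_gain - 1.0) * win
            if extra > 0:
                spikes.extend(rng.uniform(ev.onset_s, ev.offset_s + cfg.pad_s, rng.poisson(extra)))
            if cfg.locked_rate_hz > 0:
                for _ in range(rng.poisson(cfg.locked_rate_hz * win)):
                    spikes.append(ev.onset_s + rng.choice(template_lat) + rng.normal(0, cfg.jitter_sd_s))
        qc = {
            "isi_violation_index": float(rng.uniform(0.02, 0.15)),
            "amplitude_cutoff": float(rng.uniform(0.02, 0.20)),
            "presence_ratio": float(rng.uniform(0.92, 1.0)),
        }
        if i in fail_map:
            qc[fail_map[i]] = {
                "isi_violation_index": 0.40,
                "amplitude_cutoff": 0.45,
                "presence_ratio": 0.60,
            }[fail_map[i]]
        units.append(
            UnitRecord(
                unit_id=f"unit_{i:03d}",
                bird_id=f"sim_bird_{cfg.seed}",
                spike_times=np.array(sorted(t for t in spikes if 0 <= t < session_dur)),
                **qc,
            )
        )
    return units, schedule, session_dur
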