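"""Intracellular playback/perturbation statistics.

Spikes are threshold crossings 15 mV above the baseline membrane potential.
The analysis window is the call padded by 50 ms; the matched silence window
of equal length ends 50 ms before call onset.  Spiking precision is a
permutation statistic: the observed mean absolute latency difference between
spikes of distinct trials, against a null built from per-trial circular
shifts of the spike times within the window.  Subthreshold activity is the
trace with spikes clipped out and linearly interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import seconds_to_samples


@dataclass
class IntracellularTrialSet:
    """Membrane-potential traces aligned to repeated stimulus presentations.

    ``vm_mV`` is (n_trials, n_samples); all trials share the sample rate and
    the stimulus window ``[onset_s, offset_s)`` of one stimulus kind.
    """

    vm_mV: np.ndarray
    sample_rate: int
    window: tuple[float, float]
    kind: str = "playback_call"
    baseline_mV: float = -70.0
    cell_id: str = ""
    bird_id: str = ""
    age_dph: int = 0
    perturbed: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.vm_mV = np.atleast_2d(np.asarray(self.vm_mV, dtype=np.float64))
        if not np.all(np.isfinite(self.vm_mV)):
            raise ValueError("membrane potential must be finite")

    @property
    def n_trials(self) -> int:
        return self.vm_mV.shape[0]

    @property
    def threshold_mV(self) -> float:
        return self.baseline_mV + 15.0


# ---------------------------------------------------------------------------
# spikes


def detect_spikes(
    vm_mV: np.ndarray,
    sample_rate: float,
    baseline_mV: float,
    threshold_mV: float = 15.0,
    refractory_s: float = 0.001,
) -> np.ndarray:
    """Spike times (s): upward crossings of baseline + threshold, stamped at
    the crossing sample; crossings closer than the refractory gap merge."""
    vm = np.asarray(vm_mV, dtype=np.float64)
    level = baseline_mV + threshold_mV
    above = vm >= level
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0] if len(above) else False:
        crossings = np.concatenate(([0], crossings))
    times = crossings / sample_rate
    if len(times) < 2:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory_s:
            kept.append(t)
    return np.array(kept)


def stimulus_windows(
    call: tuple[float, float], pad_s: float = 0.050, gap_s: float = 0.050
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Analysis and matched silence windows for one call ``[on, off)``.

    Analysis = call duration + ``pad_s``; the silence window has the same
    length and ends ``gap_s`` before call onset to avoid overlap.
    """
    on, off = call
    if off <= on:
        raise ValueError("call window must have positive duration")
    length = off - on + pad_s
    analysis = (on, off + pad_s)
    silence = (on - gap_s - length, on - gap_s)
    if silence[0] < 0:
        raise ValueError(
            f"silence window [{silence[0]:.3f}, {silence[1]:.3f}) precedes trace start"
        )
    return analysis, silence


def firing_rate(spike_times: np.ndarray, window: tuple[float, float]) -> float:
    """Spikes with times in ``[window)`` per second of window."""
    a, b = window
    if b <= a:
        raise ValueError("window must have positive duration")
    t = np.asarray(spike_times)
    return float(np.count_nonzero((t >= a) & (t < b)) / (b - a))


# ---------------------------------------------------------------------------
# spiking precision (permutation test)


@dataclass
class PrecisionResult:
    d_obs_s: float
    null_s: np.ndarray = field(repr=False)
    score: float
    responsive: bool
    n_spikes: int
    n_trials: int


def _mean_cross_trial_latency_diff(times: np.ndarray, trial_ids: np.ndarray) -> float:
    d = np.abs(times[:, None] - times[None, :])
    cross = trial_ids[:, None] != trial_ids[None, :]
    return float(d[cross].mean()) if cross.any() else np.nan


def spiking_precision(
    trains: list[np.ndarray],
    window: tuple[float, float],
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    method: str = "circular",
    two_sided: bool = False,
) -> PrecisionResult | None:
    """Permutation test of stimulus-locked spiking precision.

    D_obs is the mean absolute latency difference over all spike pairs from
    distinct trials.  The null shuffles each trial independently: a uniform
    circular shift of its spike times within the window (``method='circular'``,
    preserves counts and ISI structure, destroys alignment) or an ISI
    permutation with a random start (``method='isi'``).  Responsive means
    D_obs falls below the null's ``alpha`` quantile (more precise than
    chance); the score is a z-score against the null, positive when precise.

    Returns ``None`` (absent, not zero) with fewer than two spiking trials.
    """
    rng = rng or np.random.default_rng(0)
    a, b = window
    T = b - a
    rel = [np.asarray(t)[(np.asarray(t) >= a) & (np.asarray(t) < b)] - a for t in trains]
    rel = [r for r in rel if len(r) > 0]
    if len(rel) < 2:
        return None
    times = np.concatenate(rel)
    ids = np.concatenate([np.full(len(r), i) for i, r in enumerate(rel)])
    d_obs = _mean_cross_trial_latency_diff(times, ids)
    n_trials = len(rel)
    cross = ids[:, None] != ids[None, :]

    null = np.empty(n_perm)
    # chunked so the (chunk, n, n) distance block stays small
    chunk = max(1, int(2_000_000 / max(1, len(times) ** 2)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        if method == "circular":
            shifts = rng.uniform(0.0, T, size=(m, n_trials))
            shifted = (times[None, :] + shifts[:, ids]) % T
        elif method == "isi":
            shifted = np.empty((m, len(times)))
            for k in range(m):
                parts = []
                for r in rel:
                    isis = np.diff(np.sort(r), prepend=0.0)
                    isis[0] = rng.uniform(0.0, T)
                    parts.append(np.cumsum(rng.permutation(isis)) % T)
                shifted[k] = np.concatenate(parts)
        else:
            raise ValueError(f"unknown shuffle method {method!r}")
        d = np.abs(shifted[:, :, None] - shifted[:, None, :])
        null[done: done + m] = d[:, cross].mean(axis=1)
        done += m

    sd = null.std(ddof=1)
    score = float((null.mean() - d_obs) / sd) if sd > 0 else 0.0
    if two_sided:
        lo, hi = np.quantile(null, [alpha / 2, 1 - alpha / 2])
        responsive = bool(d_obs < lo or d_obs > hi)
    else:
        responsive = bool(d_obs < np.quantile(null, alpha))
    return PrecisionResult(
        d_obs_s=d_obs,
        null_s=null,
        score=score,
        responsive=responsive,
        n_spikes=len(times),
        n_trials=n_trials,
    )


# ---------------------------------------------------------------------------
# subthreshold machinery


def extract_subthreshold(
    vm_mV: np.ndarray,
    baseline_mV: float,
    threshold_mV: float = 15.0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Clip spikes out of a trace and bridge the cuts by linear interpolation.

    Every maximal run of samples at or above baseline + threshold is replaced,
    from the last sub-level sample before it to the first sub-level sample
    after it, by the straight line between those anchors.  Overlapping cuts
    merge naturally.  Runs touching the trace boundary are filled from the
    single available anchor and returned as flagged segments.
    """
    vm = np.asarray(vm_mV, dtype=np.float64).copy()
    level = baseline_mV + threshold_mV
    above = vm >= level
    if not above.any():
        return vm, []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    stops = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(vm))
    flagged: list[tuple[int, int]] = []
    for a, b in zip(starts, stops):
        pre, post = a - 1, b  # anchors: last/first sub-level samples
        if pre < 0 and post >= len(vm):
            vm[:] = level
            flagged.append((0, len(vm)))
        elif pre < 0:
            vm[:post] = vm[post]
            flagged.append((0, post))
        elif post >= len(vm):
            vm[pre + 1:] = vm[pre]
            flagged.append((pre + 1, len(vm)))
        else:
            vm[pre + 1: post] = np.linspace(vm[pre], vm[post], post - pre + 1)[1:-1]
    return vm, flagged


def subthreshold_correlation(
    traces: np.ndarray,
    sample_rate: float,
    window: tuple[float, float],
) -> tuple[float, int]:
    """Mean pairwise zero-lag Pearson correlation within the window.

    Returns (mean r, number of pairs used); pairs involving a zero-variance
    trace are skipped.
    """
    X = np.atleast_2d(np.asarray(traces, dtype=np.float64))
    if X.shape[0] < 2:
        raise ValueError("need at least two traces")
    i0, i1 = seconds_to_samples(window[0], window[1], sample_rate)
    W = X[:, i0:i1]
    sd = W.std(axis=1)
    ok = sd > 0
    W = W[ok]
    if W.shape[0] < 2:
        return np.nan, 0
    Z = (W - W.mean(axis=1, keepdims=True)) / W.std(axis=1, keepdims=True)
    C = Z @ Z.T / Z.shape[1]
    iu = np.triu_indices(C.shape[0], k=1)
    return float(C[iu].mean()), len(iu[0])


def delta_subthreshold(
    traces: np.ndarray,
    sample_rate: float,
    analysis: tuple[float, float],
    silence: tuple[float, float],
) -> tuple[float, np.ndarray]:
    """Per-trial mean Vm in the analysis window minus mean Vm in the silence
    window; returns (mean over trials, per-trial values) in mV."""
    X = np.atleast_2d(np.asarray(traces, dtype=np.float64))
    a0, a1 = seconds_to_samples(analysis[0], analysis[1], sample_rate)
    s0, s1 = seconds_to_samples(silence[0], silence[1], sample_rate)
    if s0 < 0:
        raise ValueError("silence window precedes trace start")
    per_trial = X[:, a0:a1].mean(axis=1) - X[:, s0:s1].mean(axis=1)
    return float(per_trial.mean()), per_trial


# ---------------------------------------------------------------------------
# perturbation responsiveness


@dataclass
class PerturbationResult:
    deltas: np.ndarray
    control_deltas: np.ndarray
    ci: tuple[float, float]
    flags: np.ndarray
    delta_mean: float
    delta_sd: float


def perturbation_spike_delta(
    perturbed_counts: np.ndarray,
    unperturbed_counts: np.ndarray,
    ci_z: float = 1.96,
) -> PerturbationResult:
    """Spike-count change caused by a call perturbation during singing.

    Instance delta = spikes in the call epoch (+50 ms) of a perturbed
    rendition minus the mean count in the same epoch over unperturbed
    renditions.  The control distribution is built leave-one-out over the
    unperturbed renditions; the confidence interval is its mean +/- 1.96 SD,
    and instances outside it are flagged.
    """
    pert = np.asarray(perturbed_counts, dtype=float)
    ctrl = np.asarray(unperturbed_counts, dtype=float)
    if len(ctrl) < 2:
        raise ValueError("need >= 2 unperturbed renditions")
    deltas = pert - ctrl.mean()
    n = len(ctrl)
    loo_mean = (ctrl.sum() - ctrl) / (n - 1)
    control_deltas = ctrl - loo_mean
    mu = control_deltas.mean()
    sd = control_deltas.std(ddof=1)
    ci = (mu - ci_z * sd, mu + ci_z * sd)
    flags = (deltas < ci[0]) | (deltas > ci[1])
    return PerturbationResult(
        deltas=deltas,
        control_deltas=control_deltas,
        ci=ci,
        flags=flags,
        delta_mean=float(deltas.mean()) if len(deltas) else np.nan,
        delta_sd=float(deltas.std(ddof=1)) if len(deltas) > 1 else 0.0,
    )


def count_spikes_in_epoch(
    trialset: IntracellularTrialSet,
    epoch: tuple[float, float],
    threshold_mV: float = 15.0,
) -> np.ndarray:
    """Spike count per rendition inside ``[epoch)``."""
    a, b = epoch
    counts = []
    for vm in trialset.vm_mV:
        t = detect_spikes(vm, trialset.sample_rate, trialset.baseline_mV, threshold_mV)
        counts.append(np.count_nonzero((t >= a) & (t < b)))
    return np.array(counts)


def perturbation_subthreshold_flag(
    delta_mV: np.ndarray, adult_max_abs_mV: float
) -> np.ndarray:
    """Flag perturbation instances whose |delta subthreshold| strictly
    exceeds the maximum change observed in singing adults (a reference value
    supplied via configuration; it is a property of an external dataset)."""
    if adult_max_abs_mV is None or adult_max_abs_mV <= 0:
        raise ValueError(
            "adult_max_abs_mV reference is required (positive mV) to flag subthreshold changes"
        )
    return np.abs(np.asarray(delta_mV, dtype=float)) > adult_max_abs_mV
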