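"""Envelope-based vocal segmentation and song-bout assembly.

Syllables are maximal runs where a moving-RMS amplitude envelope stays at or
above threshold; a song bout is a chain of consecutive syllables spanning at
least 400 ms, ended by at least 350 ms of silence.  Calls are segmented the
same way on the backpack channel with duration bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io import AudioClip, EventTable, VocalEvent

BOUT_MIN_DUR_S = 0.400
BOUT_BREAK_S = 0.350


@dataclass
class SegmentationParams:
    """Knobs of the envelope segmenter.

    ``threshold`` is an absolute envelope level; when ``None`` the threshold
    is ``threshold_factor`` times the envelope's ``noise_percentile``-th
    percentile (a noise-floor proxy for recordings that are mostly silence).
    """

    smoothing_s: float = 0.005
    threshold: float | None = None
    threshold_factor: float = 6.0
    noise_percentile: float = 5.0
    min_syllable_dur_s: float = 0.015
    min_gap_s: float = 0.010

    def __post_init__(self) -> None:
        for name in ("smoothing_s", "threshold_factor", "min_syllable_dur_s", "min_gap_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SongBout:
    """First-syllable onset to last-syllable offset of one song."""

    onset_s: float
    offset_s: float
    syllable_indices: tuple[int, ...]

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def compute_envelope(clip: AudioClip, smoothing_s: float = 0.005) -> np.ndarray:
    """Moving-RMS amplitude envelope, same length as the input."""
    if smoothing_s <= 0:
        raise ValueError("smoothing_s must be positive")
    win = max(1, int(round(smoothing_s * clip.sample_rate)))
    if win > len(clip.samples):
        raise ValueError("smoothing window longer than clip")
    power = uniform_filter1d(clip.samples**2, size=win, mode="nearest")
    return np.sqrt(np.maximum(power, 0.0))


def _threshold_runs(env: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    above = env >= threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    stops = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(env))
    return list(zip(starts, stops))


def segment_syllables(
    clip: AudioClip,
    params: SegmentationParams | None = None,
    kind: str = "syllable",
) -> EventTable:
    """Threshold the envelope into vocal events.

    Runs separated by less than ``min_gap_s`` are merged, runs shorter than
    ``min_syllable_dur_s`` discarded; events are half-open in seconds.
    """
    params = params or SegmentationParams()
    if len(clip.samples) == 0:
        raise ValueError("cannot segment an empty clip")
    env = compute_envelope(clip, params.smoothing_s)
    thr = params.threshold
    if thr is None:
        thr = params.threshold_factor * float(np.percentile(env, params.noise_percentile))
    runs = _threshold_runs(env, thr)
    sr = clip.sample_rate
    min_gap = int(round(params.min_gap_s * sr))
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < min_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    min_dur = params.min_syllable_dur_s
    events = [
        VocalEvent(kind=kind, onset_s=a / sr, offset_s=b / sr, channel_tag=clip.channel_tag)
        for a, b in merged
        if (b - a) / sr >= min_dur and a / sr < b / sr
    ]
    return EventTable(events=events)


def detect_calls(
    clip: AudioClip,
    params: SegmentationParams | None = None,
    min_call_dur_s: float = 0.020,
    max_call_dur_s: float = 0.300,
) -> EventTable:
    """Segment the backpack channel and keep call-length events only.

    The default threshold factor is raised to 12x the noise floor: the
    backpack still picks up the juvenile at roughly -20 dB, and a higher
    threshold rejects that bleed-through while the wearer's calls sit well
    above it.
    """
    params = params or SegmentationParams(threshold_factor=12.0)
    table = segment_syllables(clip, params, kind="call")
    keep = [e for e in table.events if min_call_dur_s <= e.duration_s <= max_call_dur_s]
    return replace(table, events=keep)


def assemble_song_bouts(
    syllables: EventTable,
    bout_break_s: float = BOUT_BREAK_S,
    bout_min_dur_s: float = BOUT_MIN_DUR_S,
) -> list[SongBout]:
    """Chain syllables into song bouts.

    Consecutive syllables belong to one bout while the silent gap between
    them is strictly less than ``bout_break_s`` (a gap of at least 350 ms
    ends the song); a chain is kept as a bout only if its span, first onset
    to last offset, is at least ``bout_min_dur_s``.
    """
    ev = sorted(syllables.events, key=lambda e: e.onset_s)
    bouts: list[SongBout] = []
    chain: list[int] = []
    for i, e in enumerate(ev):
        if chain and e.onset_s - ev[chain[-1]].offset_s >= bout_break_s:
            _flush_chain(ev, chain, bouts, bout_min_dur_s)
            chain = []
        chain.append(i)
    _flush_chain(ev, chain, bouts, bout_min_dur_s)
    return bouts


def _flush_chain(ev, chain, bouts, bout_min_dur_s) -> None:
    if not chain:
        return
    onset = ev[chain[0]].onset_s
    offset = max(ev[i].offset_s for i in chain)
    if offset - onset >= bout_min_dur_s:
        bouts.append(SongBout(onset_s=onset, offset_s=offset, syllable_indices=tuple(chain)))


def attribute_calls_to_song(
    bouts: list[SongBout], calls: EventTable
) -> tuple[list[int], list[bool]]:
    """Count calls per bout; a call is practice-related iff its *onset*
    falls within a bout window ``[onset, offset)`` (the call may outlast
    the song)."""
    counts = [0] * len(bouts)
    in_song = []
    for call in calls.events:
        hit = False
        for j, b in enumerate(bouts):
            if b.onset_s <= call.onset_s < b.offset_s:
                counts[j] += 1
                hit = True
                break
        in_song.append(hit)
    return counts, in_song


def syllable_rate(syllables: EventTable) -> float:
    """Syllables per second of vocalization time, silent gaps excluded:
    count divided by the summed syllable durations."""
    if len(syllables) == 0:
        raise ValueError("syllable_rate needs at least one syllable")
    total = sum(e.duration_s for e in syllables.events)
    return len(syllables) / total


def syllable_gap_stats(
    syllables: EventTable, bouts: list[SongBout] | None = None
) -> dict[str, float | None]:
    """Mean/SD syllable duration and mean/SD inter-syllable gap.

    Gaps are the silences between consecutive syllables *within a bout*;
    with fewer than two syllables in every bout the gap statistics are
    reported as absent (``None``).
    """
    if len(syllables) == 0:
        raise ValueError("syllable_gap_stats needs at least one syllable")
    ev = sorted(syllables.events, key=lambda e: e.onset_s)
    durs = np.array([e.duration_s for e in ev])
    if bouts is None:
        bouts = assemble_song_bouts(syllables)
    gaps: list[float] = []
    for b in bouts:
        idx = list(b.syllable_indices)
        for i, j in zip(idx[:-1], idx[1:]):
            gaps.append(ev[j].onset_s - ev[i].offset_s)
    out: dict[str, float | None] = {
        "mean_syllable_dur_s": float(durs.mean()),
        "sd_syllable_dur_s": float(durs.std(ddof=1)) if len(durs) > 1 else None,
    }
    if gaps:
        g = np.array(gaps)
        out["mean_gap_s"] = float(g.mean())
        out["sd_gap_s"] = float(g.std(ddof=1)) if len(g) > 1 else None
    else:
        out["mean_gap_s"] = None
        out["sd_gap_s"] = None
    return out


def evaluate_segmentation(
    predicted: EventTable, truth: EventTable, tolerance_s: float
) -> tuple[float, float]:
    """Onset-matched precision/recall.

    One-to-one greedy matching by onset proximity within ``tolerance_s``;
    precision = matched / predicted (0 when nothing was predicted),
    recall = matched / truth.
    """
    if tolerance_s <= 0:
        raise ValueError("tolerance_s must be positive")
    pred = np.array(sorted(e.onset_s for e in predicted.events))
    true = np.array(sorted(e.onset_s for e in truth.events))
    pairs = [
        (abs(p - t), i, j)
        for i, p in enumerate(pred)
        for j, t in enumerate(true)
        if abs(p - t) <= tolerance_s
    ]
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    matched = 0
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matched += 1
    precision = matched / len(pred) if len(pred) else 0.0
    recall = matched / len(true) if len(true) else 0.0
    return precision, recall
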