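"""Readers/writers and domain containers shared by every pipeline stage.

Conventions established here and relied on everywhere else:

* times are seconds (float64) relative to recording start, intervals are
  half-open ``[onset_s, offset_s)``;
* sample indices are 0-based; seconds -> samples uses floor for onsets and
  ceil for offsets, so a segment length is never off by more than one sample;
* audio lives in WAV files (PCM16 or float32), event tables in CSV with a
  fixed column set, intracellular sweeps in an HDF5 layout, and run
  configuration in YAML.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import h5py
import yaml
from scipy.io import wavfile

EVENT_KINDS = ("syllable", "call", "song_bout", "playback_call", "playback_bos")
CHANNEL_TAGS = ("box", "backpack", "playback")

EVENT_CSV_COLUMNS = [
    "recording_id",
    "bird_id",
    "female_id",
    "age_dph",
    "channel",
    "kind",
    "onset_s",
    "offset_s",
    "label",
]

#: CSV timestamps are written with this many decimals (1e-6 s, below one
#: sample at 40 kHz, so CSV round-trips are lossless in practice).
CSV_TIME_DECIMALS = 6


def seconds_to_samples(onset_s: float, offset_s: float, sample_rate: float) -> tuple[int, int]:
    """Half-open interval in seconds -> half-open sample-index interval.

    Floor for the onset, ceil for the offset, so the samples cover the
    interval and two abutting intervals never share a sample.
    """
    i0 = int(math.floor(onset_s * sample_rate))
    i1 = int(math.ceil(offset_s * sample_rate))
    return i0, i1


# ---------------------------------------------------------------------------
# audio


@dataclass
class AudioClip:
    """Sampled sound-pressure sequence with its sample rate.

    ``samples`` are in arbitrary pressure units; integer PCM input is
    rescaled to [-1, 1] on read.
    """

    samples: np.ndarray
    sample_rate: int
    channel_tag: str = "box"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.samples.ndim != 1:
            raise ValueError("AudioClip holds a single channel (1-D samples)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def slice(self, onset_s: float, offset_s: float) -> np.ndarray:
        i0, i1 = seconds_to_samples(onset_s, offset_s, self.sample_rate)
        return self.samples[max(i0, 0): i1]


def read_audio(path: str | os.PathLike, channel: int = 0, channel_tag: str = "box") -> AudioClip:
    """Read a WAV file into an :class:`AudioClip`.

    Integer PCM is rescaled to [-1, 1] by the full scale of its dtype;
    float payloads are taken verbatim.  Multi-channel files yield the
    requested channel (default channel 0).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise ValueError(f"not a readable WAV payload: {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[:, channel]
    if data.size == 0:
        raise ValueError(f"zero-length audio: {path}")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max + 1))
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return AudioClip(samples=samples, sample_rate=int(rate), channel_tag=channel_tag)


def write_audio(clip: AudioClip, path: str | os.PathLike) -> None:
    """Write an :class:`AudioClip` as a float32 WAV file."""
    wavfile.write(path, int(clip.sample_rate), clip.samples.astype(np.float32))


# ---------------------------------------------------------------------------
# vocal events


@dataclass(frozen=True)
class VocalEvent:
    kind: str
    onset_s: float
    offset_s: float
    channel_tag: str = "box"
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not (0.0 <= self.onset_s < self.offset_s):
            raise ValueError(
                f"invalid event interval [{self.onset_s}, {self.offset_s}) for kind {self.kind!r}"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class EventTable:
    """Ordered vocal events plus session metadata.

    The lingua franca between the vocal stages: the segmenter emits one,
    bout assembly and the interaction statistics consume one.
    """

    events: list[VocalEvent] = field(default_factory=list)
    bird_id: str = ""
    female_id: str = ""
    age_dph: int = 0
    recording_id: str = ""

    def __post_init__(self) -> None:
        if self.age_dph < 0:
            raise ValueError("age_dph must be nonnegative")
        self.events = sorted(self.events, key=lambda e: (e.channel_tag, e.onset_s, e.offset_s))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def of_kind(self, *kinds: str, channel: str | None = None) -> "EventTable":
        sel = [
            e
            for e in self.events
            if e.kind in kinds and (channel is None or e.channel_tag == channel)
        ]
        return replace(self, events=sel)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "recording_id": self.recording_id,
                "bird_id": self.bird_id,
                "female_id": self.female_id,
                "age_dph": self.age_dph,
                "channel": e.channel_tag,
                "kind": e.kind,
                "onset_s": round(e.onset_s, CSV_TIME_DECIMALS),
                "offset_s": round(e.offset_s, CSV_TIME_DECIMALS),
                "label": e.label,
            }
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=EVENT_CSV_COLUMNS)


def write_event_table(table: EventTable, path: str | os.PathLike) -> None:
    df = table.to_dataframe()
    df.to_csv(path, index=False, float_format=f"%.{CSV_TIME_DECIMALS}f")


def read_event_table(path: str | os.PathLike) -> EventTable:
    """Read an event CSV, validating intervals and per-channel ordering.

    Raises ``ValueError`` naming the offending row (1-based, data rows).
    """
    df = pd.read_csv(path, dtype={"label": str}, keep_default_na=False)
    missing = [c for c in EVENT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event CSV missing columns: {missing}")
    events: list[VocalEvent] = []
    last_onset: dict[str, float] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        onset, offset = float(row.onset_s), float(row.offset_s)
        if not (0.0 <= onset < offset):
            raise ValueError(f"row {i}: invalid interval [{onset}, {offset})")
        prev = last_onset.get(row.channel)
        if prev is not None and onset < prev:
            raise ValueError(f"row {i}: events not sorted by onset within channel {row.channel!r}")
        last_onset[row.channel] = onset
        events.append(
            VocalEvent(
                kind=row.kind,
                onset_s=onset,
                offset_s=offset,
                channel_tag=row.channel,
                label=str(row.label),
            )
        )
    if len(df) == 0:
        return EventTable()
    first = df.iloc[0]
    return EventTable(
        events=events,
        bird_id=str(first["bird_id"]),
        female_id=str(first["female_id"]),
        age_dph=int(first["age_dph"]),
        recording_id=str(first["recording_id"]),
    )


# ---------------------------------------------------------------------------
# intracellular sweeps


@dataclass
class Sweep:
    """One membrane-potential sweep (mV) with its stimulus annotations."""

    vm_mV: np.ndarray
    sample_rate: int
    baseline_mV: float
    stimuli: list[VocalEvent] = field(default_factory=list)
    condition: str = "listening"

    def __post_init__(self) -> None:
        self.vm_mV = np.asarray(self.vm_mV, dtype=np.float64)
        if not np.all(np.isfinite(self.vm_mV)):
            raise ValueError("membrane potential trace must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.condition not in ("listening", "singing"):
            raise ValueError(f"unknown condition {self.condition!r}")
        dur = len(self.vm_mV) / self.sample_rate
        for ev in self.stimuli:
            if ev.kind not in ("playback_call", "playback_bos", "call"):
                raise ValueError(f"sweep stimulus must be a call/playback event, got {ev.kind!r}")
            if ev.offset_s > dur + 1e-12:
                raise ValueError(
                    f"stimulus [{ev.onset_s}, {ev.offset_s}) extends beyond trace end ({dur:.6f} s)"
                )

    @property
    def duration_s(self) -> float:
        return len(self.vm_mV) / self.sample_rate


@dataclass
class SweepStore:
    sweeps: list[Sweep]
    bird_id: str = ""
    cell_id: str = ""
    age_dph: int = 0


_STIM_DTYPE = np.dtype(
    [("kind", h5py.string_dtype()), ("onset_s", "f8"), ("offset_s", "f8")]
)


def write_sweep_store(store: SweepStore, path: str | os.PathLike) -> None:
    """HDF5 layout: /sweeps/<id>/vm (float32) + per-sweep attributes."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("sweeps")
        for i, sw in enumerate(store.sweeps):
            g = grp.create_group(f"{i:04d}")
            g.create_dataset("vm", data=sw.vm_mV.astype(np.float32))
            g.attrs["sample_rate_hz"] = int(sw.sample_rate)
            g.attrs["baseline_mV"] = float(sw.baseline_mV)
            g.attrs["bird_id"] = store.bird_id
            g.attrs["cell_id"] = store.cell_id
            g.attrs["age_dph"] = int(store.age_dph)
            g.attrs["condition"] = sw.condition
            stim = np.array(
                [(ev.kind, ev.onset_s, ev.offset_s) for ev in sw.stimuli], dtype=_STIM_DTYPE
            )
            g.create_dataset("stimuli", data=stim)


def read_sweep_store(path: str | os.PathLike) -> SweepStore:
    with h5py.File(path, "r") as f:
        grp = f["sweeps"]
        sweeps = []
        bird_id = cell_id = ""
        age = 0
        for key in sorted(grp.keys()):
            g = grp[key]
            stim_raw = g["stimuli"][()]
            stimuli = [
                VocalEvent(
                    kind=k.decode() if isinstance(k, bytes) else str(k),
                    onset_s=float(a),
                    offset_s=float(b),
                    channel_tag="playback",
                )
                for k, a, b in stim_raw
            ]
            sweeps.append(
                Sweep(
                    vm_mV=g["vm"][()].astype(np.float64),
                    sample_rate=int(g.attrs["sample_rate_hz"]),
                    baseline_mV=float(g.attrs["baseline_mV"]),
                    stimuli=stimuli,
                    condition=str(g.attrs["condition"]),
                )
            )
            bird_id = str(g.attrs["bird_id"])
            cell_id = str(g.attrs["cell_id"])
            age = int(g.attrs["age_dph"])
    return SweepStore(sweeps=sweeps, bird_id=bird_id, cell_id=cell_id, age_dph=age)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Every numeric constant of the pipeline, in one place.

    Defaults are the study's rules: 15 mV spike threshold over baseline,
    call window padded by 50 ms, bouts = >=400 ms of consecutive syllables
    ended by >=350 ms of silence, 1000 permutations, 1.96-SD confidence
    bounds, projection-neuron spontaneous rate <=2 Hz, and the unit-quality
    gates (ISI violations <=0.25, amplitude cutoff <0.3, presence >0.90).
    """

    spike_threshold_mV: float = 15.0
    response_pad_s: float = 0.050
    silence_gap_s: float = 0.050
    bout_min_dur_s: float = 0.400
    bout_break_s: float = 0.350
    snippet_dur_s: float = 0.300
    n_permutations: int = 1000
    alpha: float = 0.05
    ci_z: float = 1.96
    projection_rate_hz: float = 2.0
    qc_isi_max: float = 0.25
    qc_amp_cutoff_max: float = 0.3
    qc_presence_min: float = 0.90
    qc_isi_literal: bool = False
    shuffle_method: str = "circular"  # or "isi"
    precision_two_sided: bool = False
    snippet_anchor: str = "offset"  # or "onset"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        for name in (
            "spike_threshold_mV",
            "response_pad_s",
            "bout_min_dur_s",
            "bout_break_s",
            "snippet_dur_s",
            "ci_z",
            "projection_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def load_config(path: str | os.PathLike) -> RunConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(asdict(cfg), f, sort_keys=False)
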