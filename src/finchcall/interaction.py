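"""Call-practice interaction statistics.

The central quantity is the call ratio: female call onsets falling inside
song windows, per second of summed song-window duration.  Per-session
summaries feed an ordinary least-squares developmental trend (call ratio
against age in days post-hatch), and externally computed song-similarity
scores are classified against an upper confidence bound derived from
untutored birds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import EventTable
from .segment import SongBout, attribute_calls_to_song


@dataclass
class SessionSummary:
    """Per-day derived statistics for one juvenile/female pair."""

    bird_id: str
    age_dph: int
    n_bouts: int
    total_song_dur_s: float
    n_calls_in_song: int
    call_ratio: float | None
    syllable_rate: float | None = None
    n_songs_produced: int | None = None


@dataclass
class TrendResult:
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    p_value: float
    n: int
    slope_se: float
    singular: bool = False

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for the slope (n - 2 df)."""
        t = sps.t.ppf(0.5 + level / 2, self.n - 2)
        return self.slope - t * self.slope_se, self.slope + t * self.slope_se


def call_ratio(bouts: list[SongBout], calls: EventTable) -> float:
    """Calls per second of song: in-song call onsets over summed bout spans."""
    total = sum(b.duration_s for b in bouts)
    if total <= 0:
        raise ValueError("call ratio undefined: zero total song duration")
    counts, _ = attribute_calls_to_song(bouts, calls)
    return sum(counts) / total


def summarize_session(
    bird_id: str,
    age_dph: int,
    bouts: list[SongBout],
    calls: EventTable,
    syllable_rate: float | None = None,
) -> SessionSummary:
    total = sum(b.duration_s for b in bouts)
    counts, _ = attribute_calls_to_song(bouts, calls)
    ratio = sum(counts) / total if total > 0 else None
    return SessionSummary(
        bird_id=bird_id,
        age_dph=age_dph,
        n_bouts=len(bouts),
        total_song_dur_s=total,
        n_calls_in_song=sum(counts),
        call_ratio=ratio,
        syllable_rate=syllable_rate,
        n_songs_produced=len(bouts),
    )


def development_trend(summaries: list[SessionSummary]) -> TrendResult:
    """OLS of call ratio on age (days post-hatch), with R^2, F and the
    two-sided p value of the slope."""
    pts = [(s.age_dph, s.call_ratio) for s in summaries if s.call_ratio is not None]
    if len(pts) < 3:
        raise ValueError("development_trend needs >= 3 sessions with a defined call ratio")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(x) == 0:
        return TrendResult(
            slope=math.nan, intercept=math.nan, r_squared=math.nan,
            f_stat=math.nan, p_value=math.nan, n=len(x), slope_se=math.nan,
            singular=True,
        )
    if np.ptp(y) == 0:
        return TrendResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, f_stat=0.0,
            p_value=1.0, n=len(x), slope_se=0.0,
        )
    res = sps.linregress(x, y)
    r2 = res.rvalue**2
    # F for a simple regression is the squared slope t statistic
    f = (res.slope / res.stderr) ** 2 if res.stderr > 0 else math.inf
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        f_stat=float(f),
        p_value=float(res.pvalue),
        n=len(x),
        slope_se=float(res.stderr),
    )


def learner_threshold(mean_pct: float, se_pct: float, z: float = 1.96) -> float:
    """Upper bound of the 95% confidence interval of the untutored-bird
    similarity (mean + 1.96 SE), reported to one decimal."""
    if se_pct < 0:
        raise ValueError("se_pct must be nonnegative")
    return round(mean_pct + z * se_pct, 1)


def classify_learner(similarity_pct: float, threshold_pct: float) -> str:
    """'good' iff the bird's similarity strictly exceeds the threshold;
    a tie is classed 'poor' (the threshold is an upper confidence bound on
    no learning)."""
    return "good" if similarity_pct > threshold_pct else "poor"


@dataclass(frozen=True)
class Snippet:
    """A 300 ms post-call song snippet and its matched unperturbed control."""

    perturbed: tuple[float, float]
    control: tuple[float, float] | None
    bout_index: int
    control_bout_index: int | None
    short: bool
    has_next_syllable: bool | None


def extract_post_call_snippets(
    bouts: list[SongBout],
    calls: EventTable,
    syllables: EventTable | None = None,
    snippet_dur_s: float = 0.300,
    anchor: str = "offset",
    rng: np.random.Generator | None = None,
) -> list[Snippet]:
    """Extract post-call snippets and matched controls.

    The perturbed snippet starts directly after the female call (at the
    call offset by default, the onset via ``anchor='onset'``) and runs for
    ``snippet_dur_s``, clipped at the bout end (clipped snippets are flagged
    ``short``).  The control is the same within-bout offset applied to the
    nearest-in-time call-free bout long enough to host it; ties are broken
    by a seedable random choice.
    """
    if anchor not in ("offset", "onset"):
        raise ValueError("anchor must be 'offset' or 'onset'")
    rng = rng or np.random.default_rng(0)
    counts, _ = attribute_calls_to_song(bouts, calls)
    call_free = [j for j, c in enumerate(counts) if c == 0]
    snippets: list[Snippet] = []
    for call in calls.events:
        host = next(
            (j for j, b in enumerate(bouts) if b.onset_s <= call.onset_s < b.offset_s), None
        )
        if host is None:
            continue
        b = bouts[host]
        origin = call.offset_s if anchor == "offset" else call.onset_s
        origin = min(max(origin, b.onset_s), b.offset_s)
        end = min(origin + snippet_dur_s, b.offset_s)
        short = end - origin < snippet_dur_s - 1e-9
        rel = origin - b.onset_s
        donors = [j for j in call_free if bouts[j].duration_s >= rel + snippet_dur_s]
        ctrl_idx: int | None = None
        if donors:
            dist = np.array([abs(bouts[j].onset_s - b.onset_s) for j in donors])
            best = np.flatnonzero(dist == dist.min())
            ctrl_idx = donors[int(rng.choice(best))]
        ctrl = None
        if ctrl_idx is not None:
            c0 = bouts[ctrl_idx].onset_s + rel
            ctrl = (c0, c0 + snippet_dur_s)
        has_next = None
        if syllables is not None:
            has_next = any(origin <= e.onset_s < end for e in syllables.events)
        snippets.append(
            Snippet(
                perturbed=(origin, end),
                control=ctrl,
                bout_index=host,
                control_bout_index=ctrl_idx,
                short=short,
                has_next_syllable=has_next,
            )
        )
    return snippets
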