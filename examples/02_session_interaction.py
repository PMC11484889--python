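"""Segment one simulated two-microphone session and compute the call ratio.

A box microphone hears everything; the female's backpack microphone hears
her calls loudly and the juvenile faintly.  Syllables are segmented from the
box channel, calls from the backpack channel, bouts are assembled (>= 400 ms
of consecutive syllables, ended by >= 350 ms silence), and a call counts as
practice-related iff its onset falls inside a bout window.
"""

import finchcall as fc

cfg = fc.SessionSimConfig(session_dur_s=60, call_base_rate_hz=0.8, seed=11)
box, backpack, truth = fc.simulate_session(cfg)

syllables = fc.segment_syllables(box)
calls = fc.detect_calls(backpack)
bouts = fc.assemble_song_bouts(syllables)
print(f"detected {len(syllables)} syllables, {len(calls)} calls, {len(bouts)} bouts")

counts, in_song = fc.attribute_calls_to_song(bouts, calls)
ratio = fc.call_ratio(bouts, calls)
song_dur = sum(b.duration_s for b in bouts)
print(f"in-song calls: {sum(counts)} over {song_dur:.1f} s of song")
print(f"call ratio: {ratio:.3f} calls/s (generator in-song rate: "
      f"{cfg.call_rate_in_song_hz():.2f} Hz)")

snips = fc.extract_post_call_snippets(bouts, calls, syllables=syllables)
full = [s for s in snips if not s.short]
print(f"post-call snippets: {len(snips)} ({len(full)} full 300 ms, "
      f"{sum(1 for s in snips if s.control is not None)} with matched controls)")

# how well did segmentation do against ground truth?
audible = fc.EventTable(
    events=truth.of_kind("syllable").events + truth.of_kind("call").events
)
p, r = fc.evaluate_segmentation(syllables, audible, tolerance_s=0.010)
print(f"box-channel segmentation: precision {p:.2f}, recall {r:.2f} at 10 ms")
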