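"""Render the synthesized ABAB tutor playback and measure its statistics.

The tutor motif is two synthesized syllables repeated twice (A 185 ms near
2456.6 Hz, B 155 ms near 1165.4 Hz; internal gaps 119 and 124 ms).  The
envelope segmenter should recover all four syllables, and the template
statistics (mean syllable duration, mean gap, syllable rate excluding gaps)
are the reference values the learned songs are compared against.
"""

import finchcall as fc

clip, truth = fc.render_tutor_audio(sample_rate=44100, seed=0)
print(f"motif duration: {clip.duration_s:.3f} s, {len(truth)} syllables")

stats = fc.syllable_gap_stats(truth)
print(f"mean syllable duration: {stats['mean_syllable_dur_s'] * 1000:.0f} ms")
print(f"mean internal gap:      {stats['mean_gap_s'] * 1000:.0f} ms")
print(f"syllable rate:          {fc.syllable_rate(truth):.2f} syll/s")

segmented = fc.segment_syllables(clip)
print(f"\nenvelope segmentation found {len(segmented)} syllables:")
for pred, true in zip(segmented.events, truth.events):
    err = abs(pred.duration_s - true.duration_s) * 1000
    print(
        f"  {true.label}: predicted {pred.duration_s * 1000:6.1f} ms "
        f"(true {true.duration_s * 1000:.0f} ms, error {err:.1f} ms)"
    )
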