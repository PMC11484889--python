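"""Developmental trend of the call ratio, and learner classification.

A female whose calling tracks the juvenile's practice produces an in-song
call rate that rises with age; the trend is an ordinary least-squares fit of
call ratio on age (days post-hatch).  Song-similarity scores (computed
externally) classify birds as good/poor learners against the upper 95%
confidence bound of untutored-bird similarity.
"""

import finchcall as fc

template = fc.SessionSimConfig(
    call_base_rate_hz=0.5,
    call_age_slope_hz_per_day=0.02,
    call_age0_dph=60,
    session_dur_s=600,
    seed=42,
)
ages = list(range(50, 90, 2))
sessions, true_slope = fc.simulate_development(template, ages)

trend = fc.development_trend([summary for _, summary in sessions])
lo, hi = trend.slope_ci()
print(f"true slope:   {true_slope:.4f} calls/s per day")
print(f"fitted slope: {trend.slope:.4f} (95% CI [{lo:.4f}, {hi:.4f}])")
print(f"R^2 = {trend.r_squared:.3f}, F = {trend.f_stat:.2f}, p = {trend.p_value:.2e}")

# learner classification against the untutored-bird bound
threshold = fc.learner_threshold(32.023, 4.44)
print(f"\nlearner threshold (untutored mean + 1.96 SE): {threshold}%")
for bird, similarity in [("juvenile A", 58.3), ("juvenile B", 42.33), ("juvenile C", 27.0)]:
    verdict = fc.classify_learner(similarity, threshold)
    print(f"  {bird}: similarity {similarity}% -> {verdict} learner")
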