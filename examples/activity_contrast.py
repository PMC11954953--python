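"""Phase and bout activity contrasts on a simulated session.

Z-scores traces against the habituation baseline, detects supra-threshold
events, and contrasts mean z-activity between habituation and the reward
phase for cells active in either phase.
"""

import boutwise as bw
from boutwise.activity import phase_contrast, summarize_activity

session, _ = bw.simulate_session(bw.SessionConfig(n_cells=80), seed=7)
z, _ = bw.zscore_traces(session.traces, bouts=session.bouts)
summary = summarize_activity(session, z)

n_hab = int(summary["active_habituation"].sum())
n_stim = int(summary["active_stimulus"].sum())
print(f"active cells: {n_hab} in habituation, {n_stim} during reward")

contrast = phase_contrast(summary, "stimulus", "habituation", policy="union")
report = bw.stats_policy(contrast["value_a"], contrast["value_b"],
                         design="paired")
print(f"stimulus vs habituation mean z: {contrast['value_a'].mean():.3f} "
      f"vs {contrast['value_b'].mean():.3f} "
      f"({report.test_name}, p = {report.p_value:.2e}, d = {report.effect_size_d:.2f})")
print("The higher mean z during the reward phase reflects the planted "
      "bout-coupled excitation; with 10-min phases at these firing rates "
      "essentially every cell emits at least one event in each phase.")
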