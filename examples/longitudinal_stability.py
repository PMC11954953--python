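"""Generalizer/specializer fractions across two sessions.

Simulates a two-session cohort in which 60% of cells are seen in both
sessions and 30% of the shared cells switch their planted category, then
matches classified cells through the longitudinal map and reports the
stable (generalizer) vs unstable (specializer) split and its chord
structure.
"""

import pandas as pd

import boutwise as bw

cfg = bw.LongitudinalConfig(
    n_cells=150, overlap_rate=0.6, switch_prob=0.3,
    session_cfg=bw.SessionConfig(n_cells=150, fractions=(0.45, 0.45, 0.10),
                                 habituation_s=60, stimulus_s=240,
                                 simulate_traces=False),
)
sessions, lmap, truth = bw.simulate_longitudinal(cfg, seed=11)
ses_a, ses_b = sorted(truth.labels)

# classify from the planted labels here to isolate the matching machinery;
# see examples/simulate_and_classify.py for trace-based classification
cells = [f"cell{i:04d}" for i in range(150)]
df_a = pd.DataFrame({"cell": cells, "label": truth.labels[ses_a]})
df_b = pd.DataFrame({"cell": cells, "label": truth.labels[ses_b]})

pairs, info = bw.match_labels(df_a, df_b, lmap, ses_a, ses_b)
print(f"{info['n_matched']} cells followed across both sessions "
      f"({info['only_in_a']} and {info['only_in_b']} seen only once)")

report = bw.transition_fractions(pairs)
print(f"stable (generalizer): {report.stable_fraction:.2f}, "
      f"unstable (specializer): {report.unstable_fraction:.2f} "
      f"on {report.denominator} cells "
      f"({report.excluded_neutral_neutral} neutral-neutral excluded)")

chord = bw.chord_export(report.counts)
print("chord edges:", {f"{e['source'][:3]}->{e['target'][:3]}": e["count"]
                       for e in chord["edges"] if e["count"]})
print("The specializer fraction tracks the planted 30% switching rate.")
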