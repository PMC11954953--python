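"""Simulate a consumption session and recover the planted ensembles.

Generates a 10-min habituation + 10-min reward session for 150 cells with
40% positively, 20% negatively and 40% neutrally coupled neurons, then
classifies every cell against the bout regressor with a circular-shift
permutation null and compares the recovered ensemble fractions to the
planted ones.
"""

import boutwise as bw

cfg = bw.SessionConfig(n_cells=150, fractions=(0.4, 0.2, 0.4))
session, truth = bw.simulate_session(cfg, seed=42)
print(f"session: {session.traces.n_cells} cells, "
      f"{session.traces.duration_s:.0f} s at {session.traces.frame_rate:g} Hz, "
      f"{len(session.bouts.intervals)} consumption bouts")

z, degenerate = bw.zscore_traces(session.traces, bouts=session.bouts)
result = bw.classify_cells(session, z, alpha=0.05, n_perm=1000, seed=42,
                           exclude_cells=degenerate)

planted = truth.label_fractions("animal-01/water")
print("label     planted  recovered")
for label in ("positive", "negative", "neutral"):
    print(f"{label:<9} {planted[label]:7.3f}  {result.fractions[label]:9.3f}")
print("A recovered fraction within a few percentage points of the planted "
      "one means the correlation + permutation pipeline identifies the "
      "bout-coupled ensembles.")
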