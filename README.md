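# boutwise

Bout-locked analysis of single-cell calcium-imaging recordings taken
during consummatory behavior. Given extracted fluorescence traces
(cells × frames), consumption-bout annotations, and cross-session cell
identity maps, `boutwise` answers the questions a systems-neuroscience lab
asks of such data:

- **Which cells care about consumption?** Each cell's z-scored trace is
  correlated with the per-frame bout indicator, and significance is
  assessed with a circular-shift permutation null — the trace is rotated in
  time, preserving its autocorrelation, and the two-sided p-value is
  `p = (1 + #{|r_perm| ≥ |r_obs|}) / (n_perm + 1)`. Cells are labeled
  positive, negative, or neutral.
- **Is the coupling stable across sessions or stimuli?** Cells followed
  longitudinally contribute ordered label pairs; pos–pos and neg–neg pairs
  are *stable* (generalizers), the six switching categories are *unstable*
  (specializers), neutral–neutral pairs are excluded from the denominator,
  and the 3×3 transition table exports as chord-diagram data.
- **Does the population carry a decodable code?** A minimal
  time-contrastive embedding (offset-5 windows, time-delta positives,
  hybrid label conditioning) feeds a random-forest decoder on a 70/30
  split; every accuracy is contrasted with a label-shuffle distribution and
  the forest's out-of-bag error against shuffled-label forests.
- **Supporting quantifications:** phase/bout activity contrasts with
  MAD-based event detection, corrected total fluorescence
  (`CTF = IntDen − Area × background`) normalized to the injection site,
  real-time place-preference and conditioned flavor-preference indices,
  epoch-based consumption for laser OFF/ON designs, and a Shapiro–Wilk-
  gated test policy (t-test vs Mann–Whitney/Wilcoxon) reporting Cohen's d.

Because raw recordings of this kind are rarely deposited, the package
includes a synthetic-data module: inhomogeneous-Poisson firing with
multiplicative bout gains, double-exponential (GCaMP6m-like) transients,
configurable session paradigms, and longitudinal cohorts with planted
overlap and label switching — all ground truth recorded for recovery
testing. See `docs/methods.md` for the full model description.

## Worked example

```bash
python examples/simulate_and_classify.py
```

```
session: 150 cells, 1200 s at 10 Hz, 46 consumption bouts
label     planted  recovered
positive    0.400      0.407
negative    0.200      0.187
neutral     0.400      0.407
```

A 150-cell session (10 min habituation + 10 min reward) is simulated with
40/20/40% positive/negative/neutral cells; classification with 1000
circular-shift permutations at α = 0.05 recovers the planted ensemble
fractions within about one percentage point. The other scripts in
`examples/` walk through activity contrasts, longitudinal
generalizer/specializer fractions, shuffle-controlled decoding
(`examples/decode_bouts.py` prints, e.g., accuracy 0.990 actual vs 0.652
shuffled and OOB error 0.009 vs 0.211), and the closed-form behavioral
quantifications.

The same stages are available from the shell:

```bash
boutwise simulate --config session.yml --seed 7 --out-dir run/
boutwise classify --traces run/traces.csv --bouts run/bouts.csv \
    --frame-rate 10 --seed 7 --out run/classification.csv
```

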