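"""Shuffle-controlled decoding of consumption bouts.

Trains the minimal contrastive embedding on a simulated session, decodes
bout vs non-bout frames with a random forest on a 70/30 split, and
contrasts the accuracy and out-of-bag error against label shuffles.
"""

import boutwise as bw

cfg = bw.SessionConfig(n_cells=40, habituation_s=120, stimulus_s=360)
session, _ = bw.simulate_session(cfg, seed=5)
z, _ = bw.zscore_traces(session.traces, bouts=session.bouts)

emb = bw.train_embedding(
    z, bw.bout_labels(session),
    bw.EmbeddingConfig(iterations=800, learning_rate=1e-3, batch_size=600,
                       seed=5),
)
report = bw.decode_embedding(emb, n_perm=500, seed=5)

print(f"decoding accuracy: {report.accuracy_actual:.3f} actual vs "
      f"{report.accuracy_shuffled_mean:.3f} mean of {report.n_perm} shuffles "
      f"(95% shuffle band {report.accuracy_shuffled_q025:.3f}-"
      f"{report.accuracy_shuffled_q975:.3f})")
print(f"out-of-bag error: {report.oob_actual:.3f} actual vs "
      f"{report.oob_shuffled:.3f} with shuffled labels")
print("Accuracy far above the shuffle band and a much lower OOB error mean "
      "the population carries a real consumption code, not class-imbalance "
      "artifact.")
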