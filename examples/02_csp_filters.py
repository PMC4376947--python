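"""Fit Common Spatial Patterns on one block and inspect the filters.

After resampling to 128 Hz, common-average referencing and 8-30 Hz
zero-phase filtering, CSP simultaneously diagonalizes the two class-mean
covariance matrices.  The paired eigenvalues sum to one: a spatial
direction with high rest-class variance has low imagery-class variance —
exactly where the event-related desynchronization lives.
"""

import numpy as np

import pupilbci as pb

session = pb.generate_session(pb.SynthConfig(erd_depth=0.6), seed=2)
processed = pb.preprocess_session(session)
trials, _ = pb.epoch_session(processed)

left = [t.eeg_epoch for t in trials if t.class_label == "left"]
rest = [t.eeg_epoch for t in trials if t.class_label == "nothing"]
model = pb.fit_csp(left, rest, m=3, channel_labels=session.channel_labels)

print("retained filter pairs m =", model.m,
      "-> feature length", model.n_features)
print("top paired eigenvalues (rest, imagery):")
for i in model.selected_filters[:3]:
    print(f"  lambda_nt={model.lambda_nt[i]:.3f}  lambda_l={model.lambda_l[i]:.3f}")
print("pairing identity max |lambda_nt + lambda_l - 1| =",
      f"{np.abs(model.lambda_nt + model.lambda_l - 1).max():.2e}")

feats = np.array([pb.csp_features(model, t.eeg_epoch) for t in trials])
print("log-variance features, shape", feats.shape,
      "(exp of each row sums to", f"{np.exp(feats[0]).sum():.3f})")

# the leading pattern is the scalp map of the suppressed mu source
table = pb.pattern_table(model)
top = table.iloc[:, 1].abs()
print("largest-amplitude channel of the top pattern:",
      table["channel"][top.idxmax()], "(planted source sits over C4)")
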