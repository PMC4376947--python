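"""Extract the task-evoked pupil feature and classify by threshold.

Each trial's binocular-average diameter is baselined against the 2 s
before the go cue; the mean over the 0.5-6 s active window is the pupil
feature.  A trial whose mean exceeds the midpoint of the two class
averages is called imagery — no training data needed beyond two numbers.
"""

import numpy as np

import pupilbci as pb

session = pb.generate_session(pb.SynthConfig(), seed=3)
trials, _ = pb.epoch_session(session)

table = pb.pupil_feature_table(trials)
usable = table[table["usable"]]
by_class = usable.groupby("class_label")["mean"].mean()
print("per-class average of the baselined trial mean (mm):")
print(by_class.to_string())

threshold = pb.midpoint_threshold(by_class["left"], by_class["nothing"])
print(f"midpoint threshold: {threshold:.3f} mm")

preds = [pb.pupil_threshold_classify(v, threshold) for v in usable["mean"]]
acc = np.mean([p == t for p, t in zip(preds, usable["class_label"])])
print(f"threshold classification accuracy on this block: {acc:.1%}")
print("(resubstitution on one block; see 04 for cross-validated numbers)")
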