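"""Generate one synthetic recording block and look at what is in it.

A block is 5 minutes long: 25 auditory go cues ("left" = imagine left-hand
grasping, "nothing" = rest) 12 s apart, each followed 6 s later by a stop
cue.  EEG (32 channels, 512 Hz) carries a planted mu/beta desynchronization
during imagery; the pupil series (30 Hz, both eyes, with blink gaps)
carries a ~0.16 mm task-evoked dilation.
"""

import numpy as np

import pupilbci as pb

session = pb.generate_session(pb.SynthConfig(), seed=1)
print(f"block '{session.block_id}': {session.duration:.0f} s, "
      f"{session.eeg.shape[0]} EEG channels at {session.eeg_rate:.0f} Hz")
cues = session.go_cues()
labels = [lab for _, lab in cues]
print(f"{len(cues)} trials: {labels.count('left')} imagery, "
      f"{labels.count('nothing')} rest")
n_gap = int(np.isnan(session.pupil_left).sum())
print(f"pupil: {session.pupil_left.size} samples/eye, "
      f"{n_gap} blink-masked ({100 * n_gap / session.pupil_left.size:.1f} %)")

# round-trip through the native container
pb.write_session(session, "/tmp/example_block.h5")
again = pb.read_session("/tmp/example_block.h5")
print("container round-trip identical:", pb.sessions_equal(session, again))
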