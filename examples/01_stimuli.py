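"""Build a paired two-modality stimulus stream and inspect its annotations.

Three chunks (apple, grape, banana) — each a letter string on the text-tone
channel paired with a procedural image scanned into a 30-dimensional series
— are interleaved with random separators (random letters + noise images).
"""

import numpy as np

from comodal import ScheduleParams, StimulusParams, build_sequence, default_chunks

track = build_sequence(ScheduleParams(C=11, seed=0), default_chunks(),
                       StimulusParams())

print(f"track: {track.n_steps} steps of {track.dt} ms, "
      f"modalities {track.modality1.shape[1]} x {track.modality2.shape[1]} lines")
print(track.annotations.to_string(index=False))

# Each chunk epoch activates exactly the letter lines of its word:
apple = track.annotations[track.annotations.label == "apple"]
if len(apple):
    seg = track.modality1[track.epoch_slice(apple.iloc[0])]
    lines = sorted({chr(ord("a") + i) for i in np.flatnonzero(seg.any(axis=0))})
    print(f"\nletter lines active during an 'apple' epoch: {lines}")
    # expected: a, e, l, p — the distinct letters of "apple"
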