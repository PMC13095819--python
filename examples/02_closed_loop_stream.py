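"""Closed-loop streaming: decode a scripted mental-state sequence at 16
decisions per second and validate it as a neurofeedback exercise.

The simulated subject performs right-hand imagery for 6 s, relaxes for
3 s, then performs left-hand imagery — the classic alternation exercise.
The stream decoder slides a 2-s window in 62.5 ms steps using only past
samples; the dwell rule credits each correct decision with one step
toward the segment's required hold.
"""

import mibci

cfg = mibci.SynthEegConfig(n_series=3, trials_per_task=3, erd_depth=0.6,
                           snr=6.0, seed=7)
calib = mibci.generate_mi_session(cfg)
windows, _ = mibci.reject_outlier_windows(
    mibci.epoch_and_window(mibci.bandpass_fir(calib)))
model = mibci.fit_decoder(windows)

exercise = mibci.Exercise(sequence=[("right_hand", 6.0), ("relax", 3.0),
                                    ("left_hand", 3.0)], allotted_time=24.0)
script = [("right_hand", 8.0), ("relax", 5.0), ("left_hand", 11.0)]
rec = mibci.generate_scripted_recording(script, config=cfg, seed=99)

stream = mibci.stream_decode(rec, model)
print(f"{len(stream)} decisions over {rec.duration:.1f} s "
      f"({1 / stream.step:.0f} per second)")

result = mibci.evaluate_exercise(stream, exercise)
print(f"exercise success: {result.success}; "
      f"completion {result.completion_time and round(result.completion_time, 2)} s "
      f"of {exercise.allotted_time:.0f} s allotted")
print(f"difficulty score: {mibci.difficulty_score(exercise):.2f} "
      "(states x holds/allotted)")
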