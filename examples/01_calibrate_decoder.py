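"""Open-loop calibration: from a synthetic motor-imagery session to a
cross-validated CSP-LDA decoder and the 70% competence gate.

Generates a 3-class session (relax / left hand / right hand) with 50%
mu/beta power attenuation contralateral to the imagined hand, runs the
calibration chain and prints the run-wise fold accuracies.  Accuracy is
the fraction of correct 2-s window decisions; the gate is the study's
inclusion criterion for BCI-controllable participants.
"""

import mibci

cfg = mibci.SynthEegConfig(n_series=6, trials_per_task=6, erd_depth=0.5,
                           snr=4.0, seed=42)
rec = mibci.generate_mi_session(cfg)
print(f"session: {rec.n_channels} channels, {rec.duration:.0f} s, "
      f"{len(rec.annotations)} cued trials")

filtered = mibci.bandpass_fir(rec)                      # 8-30 Hz FIR
windows = mibci.epoch_and_window(filtered)              # 1-6 s, 2-s windows
kept, report = mibci.reject_outlier_windows(windows)
print(f"windows: {report['n_total']} extracted, "
      f"{report['n_rejected']} rejected as outliers")

cv = mibci.cross_validate(kept)                         # k = number of runs
print(f"{cv.k}-fold run-wise CV accuracies: "
      + ", ".join(f"{a:.2f}" for a in cv.fold_accuracies))
gate = mibci.competence_gate(cv)
print(f"mean accuracy {cv.mean_accuracy:.3f} -> "
      f"{'PASS' if gate.passed else 'FAIL'} vs gate {gate.threshold:.2f}")

model = mibci.fit_decoder(kept)
print(f"fitted decoder: {model.bank.n_components} CSP components, "
      f"classes {model.classes}, training accuracy "
      f"{model.training_accuracy:.3f}")
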