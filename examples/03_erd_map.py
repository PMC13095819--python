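"""ERD/ERS mapping: visualize the contralateral mu-power drop that makes
motor imagery decodable.

Computes DPSS multitaper time-frequency maps at C3/Cz/C4 for left-hand
imagery trials, expressed as percent change from the -1..0 s pre-cue
baseline.  With 40% mu-band attenuation injected at C4 the map should
read about -40% over 8-12 Hz during the 1-6 s task interval, and be far
weaker over the ipsilateral cortex (C3).
"""

import mibci

cfg = mibci.SynthEegConfig(n_series=9, trials_per_task=6, erd_depth=0.4,
                           snr=4.0, seed=1)
rec = mibci.generate_mi_session(cfg)

tf = mibci.compute_erd_map(rec, task="left_hand", channels=("C3", "Cz", "C4"))
print(f"map: {tf.values.shape[1]} frequencies x {tf.values.shape[2]} time "
      f"bins per channel, baseline {tf.baseline_interval} s")
for ch in tf.channel_names:
    mu = tf.band_mean(ch, (8, 12), (1, 6))
    print(f"  {ch}: mean mu-band (8-12 Hz) change over 1-6 s = {mu:+6.1f} %")
print("negative = event-related desynchronization; the effect is strongest "
      "over the cortex contralateral to the imagined hand")
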