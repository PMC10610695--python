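# The default4 process sampled at 25 Hz (cross-domain transfer target).
# Harmonics above the 12.5 Hz Nyquist are omitted.
n_classes: 4
segments_per_class: 15
segment_length_range: [300, 600]
sampling_rate_hz: 25.0
noise_sigma: 0.3
phase_mode: per_segment
seed: 0
class_names: [slow_sway, walk_like, jog_like, skip_like]
class_signatures:
  - - [[1.0, 1.0], [2.0, 0.2]]
    - [[1.0, 0.6]]
    - [[1.0, 0.3], [3.0, 0.1]]
  - - [[2.0, 0.8], [4.0, 0.3]]
    - [[2.0, 1.0]]
    - [[2.0, 0.4], [6.0, 0.15]]
  - - [[3.5, 0.9], [7.0, 0.25]]
    - [[3.5, 0.5], [10.5, 0.1]]
    - [[3.5, 1.1]]
  - - [[5.0, 0.7], [10.0, 0.35]]
    - [[5.0, 1.0]]
    - [[5.0, 0.5]]
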