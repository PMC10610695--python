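# Four activity-like classes at 50 Hz with well-separated fundamentals.
# class_signatures[class][axis] = [[frequency_hz, amplitude], ...]
n_classes: 4
segments_per_class: 15
segment_length_range: [400, 900]
sampling_rate_hz: 50.0
noise_sigma: 0.3
phase_mode: per_segment
seed: 0
class_names: [slow_sway, walk_like, jog_like, skip_like]
class_signatures:
  - # slow_sway: 1.0 Hz fundamental
    - [[1.0, 1.0], [2.0, 0.2]]
    - [[1.0, 0.6]]
    - [[1.0, 0.3], [3.0, 0.1]]
  - # walk_like: 2.0 Hz fundamental
    - [[2.0, 0.8], [4.0, 0.3]]
    - [[2.0, 1.0]]
    - [[2.0, 0.4], [6.0, 0.15]]
  - # jog_like: 3.5 Hz fundamental
    - [[3.5, 0.9], [7.0, 0.25]]
    - [[3.5, 0.5], [10.5, 0.1]]
    - [[3.5, 1.1]]
  - # skip_like: 5.0 Hz fundamental
    - [[5.0, 0.7], [10.0, 0.35]]
    - [[5.0, 1.0], [15.0, 0.1]]
    - [[5.0, 0.5]]
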