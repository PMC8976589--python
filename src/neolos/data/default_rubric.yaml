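# Default cut-off configuration for the composite severity score.
#
# Each graded component maps to an ordered list of [lower_bound, score]
# pairs covering [0, inf); a value receives the score of the last bin
# whose lower bound is <= value (lower-bound-inclusive binning).
#
# The WBC normal band is closed on both sides, [4, 20] x10^9/L: the
# upper abnormal bin therefore starts at the smallest float above 20.
#
# S/F is SpO2 (percent) divided by FiO2 (fraction).
bins:
  wbc:
    - [0, 1]
    - [4, 0]
    - [20.000000000000004, 1]
  plt:
    - [0, 3]
    - [50, 2]
    - [100, 1]
    - [150, 0]
  crp:
    - [0, 0]
    - [10, 1]
    - [30, 2]
    - [50, 3]
  sf:
    - [0, 4]
    - [100, 3]
    - [150, 2]
    - [200, 1]
    - [300, 0]
vent_scores:
  none: 0
  non_invasive: 1
  invasive: 2
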