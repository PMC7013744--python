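"""Published per-setting classification accuracies of the original study.

The clinical four-setting breast-ultrasound dataset is private, so these
printed accuracy rates (percent, one entry per acquisition setting) are
shipped as reference inputs: summary statistics — means, extremes,
standard deviations, between-method differences and the consistency
fitness — are recomputed from them at run time rather than quoted.
"""

from __future__ import annotations

#: universal feature subsets of size k, accuracy % per setting 1..4
UNIVERSAL_ACCURACY_PCT = {
    5: (98.42, 96.81, 97.52, 94.27),
    10: (98.35, 98.86, 98.27, 95.81),
    15: (99.14, 98.48, 98.27, 96.02),
}

#: per-setting best subsets of size k, accuracy % per setting 1..4
INDIVIDUAL_ACCURACY_PCT = {
    5: (99.00, 97.17, 98.04, 96.91),
    10: (99.34, 98.94, 98.42, 96.86),
    15: (99.27, 98.94, 98.38, 96.31),
}

#: 10-feature comparison across methods, accuracy % per setting 1..4
COMPARISON_ACCURACY_PCT = {
    "ga_svm": (98.35, 98.86, 98.27, 95.81),
    "chang": (99.80, 97.79, 97.76, 95.09),
    "xie": (95.87, 96.23, 96.72, 92.12),
}

#: the 10-feature universal subset as published
UNIVERSAL_SUBSET_10 = ("F4", "F5", "F22", "F26", "F30", "F95", "F108", "F109", "F113", "F124")
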