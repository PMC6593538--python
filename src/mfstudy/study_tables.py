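"""Printed summary tables of the multi-scanner mitotic-figure reader study.

This package's design follows a published validation study in which five
pathologists marked mitotic figures in 40 ROIs on four canine oral melanoma
slides, once under a brightfield microscope and once on each of four
whole-slide scanners.  The study printed its per-reader candidate counts,
pairwise kappa tables, accuracy table and comparison p-values, but not the
raw per-candidate marks; these transcriptions make the printed numbers
available as inputs to worked examples (reader averaging, kappa extrema,
Holm decisions, consensus arithmetic) that are closed over them.
"""

from __future__ import annotations

import numpy as np

READERS = ["Observer 1", "Observer 2", "Observer 3", "Observer 4", "Observer 5"]
MODALITIES = ["Scanner A", "Scanner B", "Scanner C", "Scanner D", "Microscope"]
REFERENCE = "Microscope"

POOL_SIZE = 155  # candidates marked by anyone, anywhere
TRUE_MFS = 74  # adjudicated true mitotic figures
AUTO_CONSENSUS_TRUE = 37  # accepted by >=4 of 5 microscope readers
WSI_ONLY_CANDIDATES = 60  # never marked under the microscope
WSI_ONLY_TRUE = 4  # of those, adjudicated true by the panel

# Candidates marked by exactly k of the 5 microscope readers.
MICROSCOPE_MULTIPLICITY = {1: 28, 2: 13, 3: 17, 4: 8, 5: 29}

# Whole-study candidate counts per reader (rows) and modality (columns).
CANDIDATE_COUNTS = np.array(
    [
        [43, 57, 35, 42, 41],
        [64, 49, 28, 41, 66],
        [55, 39, 36, 60, 51],
        [34, 43, 39, 34, 64],
        [35, 48, 39, 46, 60],
    ]
)

# Inter-observer kappas: rows are the 10 unordered reader pairs, columns MODALITIES.
INTER_OBSERVER_PAIRS = [
    ("Observer 1", "Observer 2"),
    ("Observer 1", "Observer 3"),
    ("Observer 1", "Observer 4"),
    ("Observer 1", "Observer 5"),
    ("Observer 2", "Observer 3"),
    ("Observer 2", "Observer 4"),
    ("Observer 2", "Observer 5"),
    ("Observer 3", "Observer 4"),
    ("Observer 3", "Observer 5"),
    ("Observer 4", "Observer 5"),
]
INTER_OBSERVER_KAPPA = np.array(
    [
        [0.677, 0.770, 0.814, 0.815, 0.735],
        [0.775, 0.790, 0.872, 0.745, 0.833],
        [0.885, 0.788, 0.852, 0.865, 0.779],
        [0.864, 0.799, 0.879, 0.820, 0.781],
        [0.621, 0.807, 0.834, 0.667, 0.742],
        [0.693, 0.763, 0.840, 0.791, 0.723],
        [0.699, 0.802, 0.840, 0.786, 0.666],
        [0.773, 0.850, 0.818, 0.819, 0.831],
        [0.765, 0.862, 0.845, 0.785, 0.789],
        [0.886, 0.833, 0.864, 0.905, 0.743],
    ]
)

# Intra-observer kappas: rows are the 10 unordered modality pairs, columns READERS.
INTRA_OBSERVER_PAIRS = [
    ("Scanner A", "Microscope"),
    ("Scanner B", "Microscope"),
    ("Scanner C", "Microscope"),
    ("Scanner D", "Microscope"),
    ("Scanner A", "Scanner B"),
    ("Scanner A", "Scanner C"),
    ("Scanner A", "Scanner D"),
    ("Scanner B", "Scanner C"),
    ("Scanner B", "Scanner D"),
    ("Scanner C", "Scanner D"),
]
INTRA_OBSERVER_KAPPA = np.array(
    [
        [0.835, 0.677, 0.784, 0.748, 0.830],
        [0.775, 0.729, 0.861, 0.763, 0.797],
        [0.824, 0.717, 0.814, 0.738, 0.726],
        [0.815, 0.664, 0.804, 0.776, 0.799],
        [0.816, 0.745, 0.777, 0.858, 0.808],
        [0.851, 0.704, 0.744, 0.859, 0.892],
        [0.856, 0.594, 0.728, 0.880, 0.742],
        [0.792, 0.784, 0.939, 0.891, 0.848],
        [0.810, 0.709, 0.852, 0.871, 0.761],
        [0.831, 0.772, 0.832, 0.872, 0.754],
    ]
)

# Accuracy = (Se+Sp)/2 per reader (rows) and modality (columns).
ACCURACY = np.array(
    [
        [0.713, 0.743, 0.685, 0.706, 0.764],
        [0.700, 0.715, 0.631, 0.648, 0.778],
        [0.704, 0.738, 0.717, 0.802, 0.806],
        [0.691, 0.726, 0.699, 0.717, 0.842],
        [0.698, 0.754, 0.738, 0.785, 0.802],
    ]
)

# Two-sided p-values of the scanner-vs-microscope comparisons, scanner A..D.
COMPARISON_PVALUES = [0.001, 0.009, 0.001, 0.062]
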