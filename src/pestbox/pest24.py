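"""Class vocabulary and published per-class instance counts of the Pest24
multi-class insect-trap benchmark (24 pest categories monitored by the
Chinese Ministry of Agriculture).

The instance counts drive the default class-imbalance weights of the
synthetic scene generator: the most abundant class (Anomala corpulenta,
53,347 instances) outnumbers the rarest (Holotrichia oblita, 108) by
nearly 500x, which is exactly the regime a focal objectness loss targets.

Class ids in this package are 0-based; the benchmark's published tables
number classes from 1.
"""

from __future__ import annotations

import numpy as np

PEST24_CLASS_NAMES: tuple[str, ...] = (
    "Rice planthopper",
    "Rice Leaf Roller",
    "Chilo suppressalis",
    "Armyworm",
    "Bollworm",
    "Meadow borer",
    "Athetis lepigone",
    "Spodoptera litura",
    "Spodoptera exigua",
    "Stem borer",
    "Little Gecko",
    "Plutella xylostella",
    "Spodoptera cabbage",
    "Scotogramma trifolii Rottemberg",
    "Yellow tiger",
    "Land tiger",
    "Eight-character tiger",
    "Holotrichia oblita",
    "Holotrichia parallela",
    "Anomala corpulenta",
    "Gryllotalpa orientalis",
    "Nematode trench",
    "Agriotes fuscicollis Miwa",
    "Melahotus",
)

PEST24_INSTANCE_COUNTS: np.ndarray = np.array(
    [
        1511, 1240, 1285, 8880, 28014, 16516, 30339, 1951, 7263, 1804, 4279, 953,
        2302, 4679, 1686, 475, 168, 108, 11675, 53347, 6528, 167, 6484, 768,
    ],
    dtype=np.int64,
)

#: Minority classes augmented during training (0-based ids; published
#: 1-based indices 17, 18 and 22).
PEST24_MINORITY_CLASSES: tuple[int, ...] = (16, 17, 21)


def pest24_class_weights() -> np.ndarray:
    """Instance-count proportions, summing to 1."""
    return PEST24_INSTANCE_COUNTS / PEST24_INSTANCE_COUNTS.sum()
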