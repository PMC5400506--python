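"""Small bundled reference tables.

``liver_pair_zscores`` is the published two-way Z-score table for within-mouse
liver tumor pairs from a Mad2l1-conditional (SAC-deficient) mouse cohort:
nine animals, each contributing one benign/malignant (HCA-HCC) pair, one of
which also carried a second carcinoma (the HCC1-HCC2 row). Each tumor of a
pair was scored against its own cross-animal Jaccard null, giving two
Z-scores per pair. These printed values are the canonical worked example for
``classify_pair``: with the two-way 1.96 rule they yield exactly two strongly
related HCA-HCC pairs and one weakly related HCC-HCC pair.
"""

from __future__ import annotations

import pandas as pd

_LIVER_ROWS = [
    ("7122", "HCA1", 1.08, "HCC1", 1.36),
    ("2985", "HCA1", 1.10, "HCC1", 1.15),
    ("6717", "HCA1", 1.55, "HCC1", 1.37),
    ("6705", "HCA1", 0.13, "HCC1", 0.56),
    ("6718", "HCA1", 1.88, "HCC1", 0.46),
    ("6546", "HCA1", 1.62, "HCC1", 1.47),
    ("6891", "HCA1", 1.21, "HCC1", 1.21),
    ("6891", "HCC1", 2.81, "HCC2", 1.37),
    ("6755", "HCA1", 2.49, "HCC1", 2.69),
    ("6228", "HCA1", 2.50, "HCC1", 2.03),
]


def liver_pair_zscores() -> pd.DataFrame:
    """Two-way Z-scores for within-mouse liver tumor pairs (see module docs)."""
    return pd.DataFrame(
        _LIVER_ROWS, columns=["mouse", "tumor_a", "z_a", "tumor_b", "z_b"]
    )
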