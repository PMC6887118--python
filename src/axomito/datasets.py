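"""Bundled reference measurements used by the worked examples.

These are published measurements from NGF-treated embryonic chick sensory
axons: for each of 20 observed fission events, the length of the
mitochondrion that fissioned and the summed length of the actin patches
present on it at the first frame where fission was evident.  They drive
the worked example for the random-overlap probability statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: (mitochondrion length um, summed actin-patch length um) per fission event
_FISSION_OVERLAP_ROWS = [
    (7.17, 0.47), (6.90, 0.69), (12.00, 1.10), (8.15, 0.69), (16.78, 3.69),
    (7.35, 0.53), (3.94, 0.65), (10.24, 0.75), (9.65, 0.75), (4.10, 0.69),
    (7.48, 0.75), (6.65, 0.69), (16.78, 0.23), (5.87, 0.69), (4.70, 0.50),
    (8.30, 0.75), (6.90, 0.80), (7.70, 0.78), (11.30, 0.86), (4.40, 0.56),
]

#: fission sites observed to colocalize with a detectable actin patch,
#: out of all scored fission sites
FISSION_SITE_COLOC_COUNTS = (20, 25)

#: median axonal mitochondrion lengths (um) in cultured sensory neurons at
#: embryonic day 7 versus day 14 (24 h in NGF)
MEDIAN_LENGTH_E7_UM = 1.2
MEDIAN_LENGTH_E14_UM = 1.6


def fission_overlap_dataset() -> pd.DataFrame:
    """The 20-event reference dataset as a two-column table."""
    return pd.DataFrame(_FISSION_OVERLAP_ROWS,
                        columns=["mito_length_um", "patch_length_um"])


def fission_overlap_arrays() -> tuple[np.ndarray, np.ndarray]:
    df = fission_overlap_dataset()
    return (df["mito_length_um"].to_numpy(),
            df["patch_length_um"].to_numpy())
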