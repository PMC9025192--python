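"""Built-in datasets.

The lung-xenograft ratio table: mean tumor volumes of four patient-derived
NSCLC cell lines grown subcutaneously in mice, irradiated with two dose
levels per line (plus untreated controls), and measured by caliper 15 and
30 days after the end of irradiation.  Volumes are normalized to the volume
at the end of treatment, ``V(t*) = 1``; the ratios carry roughly 10%
experimental uncertainty (5% measurement precision per volume).
"""

from __future__ import annotations

import pandas as pd

from .cc import DoseObservation

__all__ = ["xenograft_ratio_table", "xenograft_dose_observations"]

# cell line, dose (Gy; 0 = untreated), V/V(t*) at +15 d and +30 d
_XENOGRAFT_ROWS = [
    ("L3", 0, 1.6, 1.9),
    ("L3", 5, 1.36, 1.58),
    ("L3", 8, 0.77, 0.66),
    ("L4", 0, 1.2, 1.81),
    ("L4", 8, 1.23, 1.79),
    ("L4", 10, 0.85, 0.8),
    ("L2", 0, 1.98, 2.49),
    ("L2", 5, 0.87, 0.75),
    ("L2", 10, 0.62, 0.49),
    ("L1", 0, 1.32, 2.02),
    ("L1", 5, 1.27, 1.51),
    ("L1", 10, 1.25, 1.65),
]


def xenograft_ratio_table() -> pd.DataFrame:
    """The xenograft dataset as a data frame.

    Columns: ``cell_line``, ``dose_gy`` (0 = untreated), ``ratio_d15``,
    ``ratio_d30`` (volumes in units of the end-of-treatment volume).
    """
    return pd.DataFrame(_XENOGRAFT_ROWS,
                        columns=["cell_line", "dose_gy", "ratio_d15", "ratio_d30"])


def xenograft_dose_observations() -> list[DoseObservation]:
    """The xenograft dataset as :class:`~tumorgrowth.cc.DoseObservation` rows
    (12 rows: 4 untreated, 8 treated)."""
    return [
        DoseObservation(cell_line=line, dose=float(dose), ratios={15.0: r15, 30.0: r30})
        for line, dose, r15, r30 in _XENOGRAFT_ROWS
    ]
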