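"""Bundled worked-example data.

The Box-Behnken design/response table for triclosan degradation by the
degrader strain: 15 runs over coded temperature (20/30/40 degC), pH
(5/7/9) and inoculum biomass (0.1/0.2/0.3 g/L), response in mg/L TCS
degraded from a 5 mg/L dose after 72 h.
"""

from __future__ import annotations

import numpy as np

from .doe_rsm import DEFAULT_FACTORS, DesignMatrix, ResponseTable

# run, x1 (temperature), x2 (pH), x3 (biomass), response (mg/L)
_BBD_ROWS = (
    (1, 0, 0, 0, 5.00),
    (2, 0, -1, 1, 0.85),
    (3, 1, 1, 0, 4.79),
    (4, 0, 0, 0, 5.00),
    (5, 1, 0, -1, 4.84),
    (6, 0, 1, 1, 4.72),
    (7, -1, 1, 0, 0.47),
    (8, -1, 0, -1, 0.73),
    (9, 0, 0, 0, 5.00),
    (10, 1, 0, 1, 4.89),
    (11, -1, -1, 0, 0.45),
    (12, 1, -1, 0, 0.11),
    (13, 0, 1, -1, 4.57),
    (14, 0, -1, -1, 0.89),
    (15, -1, 0, 1, 0.86),
)

TCS_DOSE_MG_PER_L = 5.0


def triclosan_bbd_table() -> ResponseTable:
    """The 15-run Box-Behnken experiment (3 center replicates)."""
    arr = np.array(_BBD_ROWS, dtype=float)
    design = DesignMatrix(factors=DEFAULT_FACTORS, runs=arr[:, 1:4])
    return ResponseTable(design=design, response=arr[:, 4])
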