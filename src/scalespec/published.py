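"""Published reference metrics for carp scaling-rate PLSR calibrations.

The original 100-sample-per-region carp experiment reported a 16-model
evaluation matrix (4 pretreatments x {FW, SPA, RC, 2D-COS}) for each body
region. Its printed rows are embedded here as plain data so the package's
metric arithmetic — the RPD identity ``RPD = 100 * SD_P / RMSEP`` and the
model-stability difference ``|RMSEC - RMSEP|`` — can be validated against
independently reported values. Row layout matches
:data:`scalespec.evaluation.REPORT_COLUMNS` minus the grade columns; SD/SE
columns are on the fractional scale as printed.

The underlying spectra were never deposited, so these rows are reference
values only: nothing in the package fits models to them.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "published_reports",
    "RPD_CONSISTENT_ROWS",
    "BACK_FW_STABILITY",
]

_COLUMNS = [
    "model",
    "n_vars",
    "R2C_pct",
    "RMSEC_pct",
    "SDC",
    "SEC",
    "R2P_pct",
    "RMSEP_pct",
    "RPD",
    "SDP",
    "SEP",
]

# fmt: off
_BACK = [
    ("SG-PLSR",         352, 98.92,  1.96, 0.19, 0.02, 96.85,  3.33,  5.41, 0.18, 0.03),
    ("FD-PLSR",         352, 99.06,  1.82, 0.18, 0.03, 99.72,  1.43, 12.59, 0.18, 0.03),
    ("MSC-PLSR",        352, 99.64,  1.63, 0.18, 0.02, 98.73,  2.42,  7.44, 0.18, 0.03),
    ("SNV-PLSR",        352, 99.43,  1.74, 0.19, 0.02, 98.16,  2.66,  7.14, 0.19, 0.03),
    ("SG-SPA-PLSR",       5, 90.63,  6.36, 0.21, 0.03, 88.23,  7.19,  2.64, 0.19, 0.03),
    ("FD-SPA-PLSR",       5, 88.92,  9.87, 0.26, 0.03, 86.93, 10.59,  2.46, 0.26, 0.03),
    ("MSC-SPA-PLSR",      6, 87.21,  6.87, 0.18, 0.02, 83.13,  7.62,  1.84, 0.14, 0.02),
    ("SNV-SPA-PLSR",      5, 95.07,  6.72, 0.25, 0.03, 93.23,  8.13,  3.44, 0.28, 0.04),
    ("SG-RC-PLSR",        4, 93.04,  8.02, 0.25, 0.03, 91.19, 10.24,  2.79, 0.29, 0.05),
    ("FD-RC-PLSR",        8, 96.23,  6.20, 0.26, 0.03, 95.55,  7.54,  3.98, 0.30, 0.05),
    ("MSC-RC-PLSR",       7, 89.01,  9.81, 0.26, 0.03, 88.76, 11.79,  2.40, 0.28, 0.04),
    ("SNV-RC-PLSR",       4, 92.82,  8.34, 0.25, 0.03, 91.17, 10.07,  3.01, 0.30, 0.05),
    ("SG-2D-COS-PLSR",    3, 44.42, 24.60, 0.27, 0.03, 42.57, 26.71,  1.09, 0.29, 0.05),
    ("FD-2D-COS-PLSR",    3, 43.60, 24.71, 0.27, 0.03, 44.24, 26.35,  1.02, 0.27, 0.03),
    ("MSC-2D-COS-PLSR",   3, 44.66, 21.96, 0.23, 0.03, 41.72, 26.90,  1.13, 0.30, 0.05),
    ("SNV-2D-COS-PLSR",   3, 45.31, 21.83, 0.21, 0.03, 40.46, 25.81,  0.85, 0.22, 0.03),
]

_BELLY = [
    ("SG-PLSR",         352, 94.01,  4.82, 0.17, 0.02, 91.06,  5.83,  2.92, 0.17, 0.03),
    ("FD-PLSR",         352, 97.32,  3.32, 0.17, 0.02, 96.67,  6.54,  2.56, 0.17, 0.03),
    ("MSC-PLSR",        352, 93.42,  4.94, 0.17, 0.02, 91.20,  5.77,  2.77, 0.16, 0.03),
    ("SNV-PLSR",        352, 99.33,  1.63, 0.27, 0.04, 98.34,  2.54, 10.24, 0.26, 0.04),
    ("SG-SPA-PLSR",       7, 92.43,  5.46, 0.19, 0.02, 89.33,  6.44,  2.80, 0.18, 0.03),
    ("FD-SPA-PLSR",       7, 92.13,  8.98, 0.25, 0.03, 91.19,  8.95,  2.79, 0.25, 0.04),
    ("MSC-SPA-PLSR",      6, 91.23,  6.26, 0.16, 0.02, 90.21,  7.02,  2.27, 0.16, 0.03),
    ("SNV-SPA-PLSR",      8, 93.44,  8.05, 0.26, 0.03, 90.81,  9.13,  3.07, 0.28, 0.04),
    ("SG-RC-PLSR",        7, 90.18,  9.76, 0.25, 0.03, 86.07, 12.19,  2.05, 0.25, 0.04),
    ("FD-RC-PLSR",        7, 90.62,  9.61, 0.25, 0.03, 87.66, 10.58,  2.36, 0.25, 0.04),
    ("MSC-RC-PLSR",       8, 91.56,  8.75, 0.27, 0.03, 88.51, 10.68,  2.43, 0.26, 0.04),
    ("SNV-RC-PLSR",       7, 89.06,  9.92, 0.26, 0.03, 85.72, 11.56,  1.73, 0.20, 0.03),
    ("SG-2D-COS-PLSR",    4, 50.50, 20.83, 0.19, 0.02, 47.28, 24.28,  0.91, 0.22, 0.03),
    ("FD-2D-COS-PLSR",    8, 91.24,  9.29, 0.25, 0.03, 87.72, 10.57,  2.37, 0.25, 0.04),
    ("MSC-2D-COS-PLSR",   5, 62.96, 18.68, 0.20, 0.03, 60.64, 19.17,  1.10, 0.21, 0.03),
    ("SNV-2D-COS-PLSR",   5, 58.99, 19.71, 0.23, 0.03, 55.61, 20.33,  1.18, 0.24, 0.04),
]

_TAIL = [
    ("SG-PLSR",         352, 97.92,  2.82, 0.20, 0.03, 96.21,  4.32,  4.86, 0.21, 0.03),
    ("FD-PLSR",         352, 98.34,  1.58, 0.20, 0.03, 98.11,  2.34,  8.55, 0.20, 0.03),
    ("MSC-PLSR",        352, 98.31,  1.53, 0.20, 0.03, 97.52,  4.07,  4.91, 0.20, 0.03),
    ("SNV-PLSR",        352, 97.82,  1.76, 0.24, 0.03, 96.15,  3.22,  7.45, 0.24, 0.04),
    ("SG-SPA-PLSR",       5, 92.16,  6.38, 0.24, 0.03, 89.27,  9.45,  2.54, 0.24, 0.04),
    ("FD-SPA-PLSR",       7, 94.78,  7.09, 0.24, 0.03, 93.30,  8.40,  2.86, 0.24, 0.04),
    ("MSC-SPA-PLSR",      5, 94.56,  7.76, 0.25, 0.03, 91.38,  9.95,  2.41, 0.24, 0.04),
    ("SNV-SPA-PLSR",      5, 89.69,  8.96, 0.27, 0.04, 87.22, 12.22,  2.29, 0.28, 0.04),
    ("SG-RC-PLSR",        8, 93.72,  7.75, 0.25, 0.03, 92.89,  9.76,  2.67, 0.26, 0.04),
    ("FD-RC-PLSR",        9, 91.43,  9.83, 0.25, 0.03, 89.52, 10.86,  2.30, 0.25, 0.04),
    ("MSC-RC-PLSR",       7, 90.90,  8.80, 0.25, 0.03, 89.86, 11.02,  2.40, 0.26, 0.04),
    ("SNV-RC-PLSR",       8, 95.34,  6.66, 0.25, 0.03, 93.71,  8.37,  3.42, 0.29, 0.05),
    ("SG-2D-COS-PLSR",    3, 54.64, 19.84, 0.24, 0.03, 53.05, 21.65,  1.12, 0.24, 0.04),
    ("FD-2D-COS-PLSR",    5, 52.62, 20.65, 0.23, 0.03, 50.71, 22.49,  1.02, 0.23, 0.04),
    ("MSC-2D-COS-PLSR",   4, 63.81, 18.55, 0.23, 0.03, 59.71, 20.12,  1.25, 0.25, 0.04),
    ("SNV-2D-COS-PLSR",   4, 63.53, 17.48, 0.21, 0.03, 59.88, 20.02,  1.16, 0.23, 0.04),
]
# fmt: on

_TABLES = {"back": _BACK, "belly": _BELLY, "tail": _TAIL}

#: (region, model) rows whose printed RPD reproduces ``100 * SD_P / RMSEP``
#: at 2-dp rounding. Not every printed RPD cell satisfies the identity
#: (independent rounding in the source); these six do.
RPD_CONSISTENT_ROWS = (
    ("back", "SG-PLSR"),
    ("back", "FD-PLSR"),
    ("back", "FD-RC-PLSR"),
    ("belly", "SNV-PLSR"),
    ("belly", "SNV-SPA-PLSR"),
    ("tail", "FD-PLSR"),
)

#: Reported |RMSEC - RMSEP| stability of the four back-region full-wavelength
#: models, in percent, keyed by pretreatment.
BACK_FW_STABILITY = {"SG": 1.37, "FD": 0.39, "MSC": 0.79, "SNV": 0.92}


def published_reports(region: str) -> pd.DataFrame:
    """Reference evaluation rows for one body region (back, belly or tail)."""
    try:
        rows = _TABLES[region]
    except KeyError:
        raise ValueError(
            f"unknown region {region!r}; expected one of {sorted(_TABLES)}"
        ) from None
    return pd.DataFrame(rows, columns=_COLUMNS)
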