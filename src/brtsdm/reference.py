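"""Published reference values for the 15-predictor distribution model.

These are the relative contributions (RC, %) and the predictor grouping of
the original field-data model for *Gentiana dahurica*, kept here as named
constants.  They serve as fixed inputs to the selection and grouping
operations (e.g. choosing the main ecological factors with RC > 2%) and as
arithmetic fixtures; the pipeline's own RC values are recomputed from data
at run time.
"""

from __future__ import annotations

__all__ = ["REFERENCE_RC", "REFERENCE_FACTOR_GROUPS", "REFERENCE_KINDS"]

# predictor -> relative contribution (%); values total 100.001 due to rounding
REFERENCE_RC: dict[str, float] = {
    "BIO1": 4.577,      # annual mean temperature
    "BIO2": 0.539,      # mean diurnal temperature range
    "BIO3": 10.091,     # temperature seasonality (sd x 100)
    "BIO4": 14.567,     # annual precipitation
    "BIO5": 0.577,      # precipitation seasonality (CV)
    "Srad": 1.026,      # mean solar radiation
    "Elev": 30.188,     # elevation
    "Zblx": 5.071,      # vegetation type (categorical)
    "SOI1": 1.652,      # soil sand content
    "SOI2": 0.019,      # soil moisture content (categorical)
    "SOI3": 0.004,      # soil clay content
    "SOI4": 28.974,     # soil type (categorical)
    "SOI5": 0.148,      # cation exchange capacity
    "SOI6": 0.091,      # soil organic carbon content
    "Suntime": 2.477,   # annual sunshine duration
}

# factor-type grouping as tabulated (blank rows inherit the group above them)
REFERENCE_FACTOR_GROUPS: dict[str, str] = {
    "BIO1": "climatic",
    "BIO2": "climatic",
    "BIO3": "climatic",
    "BIO4": "climatic",
    "BIO5": "climatic",
    "Srad": "solar radiation",
    "Elev": "terrain",
    "Zblx": "terrain",
    "SOI1": "soil",
    "SOI2": "soil",
    "SOI3": "soil",
    "SOI4": "soil",
    "SOI5": "soil",
    "SOI6": "soil",
    "Suntime": "climatic",
}

REFERENCE_KINDS: dict[str, str] = {
    name: ("categorical" if name in ("Zblx", "SOI2", "SOI4") else "continuous")
    for name in REFERENCE_RC
}
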