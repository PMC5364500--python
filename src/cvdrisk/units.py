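"""Unit conversion between conventional (mg/dL) and SI (mmol/L) lab units.

The cohort schema stores lipids and glucose in mmol/L (SI); several risk
equations expect mg/dL. Conversion uses the standard molar-mass constants:
cholesterol 386.65 g/mol and glucose 180.16 g/mol, i.e. 38.67 and
18.02 mg/dL per mmol/L.
"""

from __future__ import annotations

# mg/dL per mmol/L
CONVERSION_FACTORS = {
    "TC": 38.67,
    "HDL": 38.67,
    "glucose": 18.02,
}

#: quantities measured in cholesterol units
_ALIASES = {
    "total_cholesterol": "TC",
    "hdl": "HDL",
    "tc": "TC",
}

VALID_TARGETS = ("mg/dL", "mmol/L")


def convert_units(value, quantity: str, target: str):
    """Convert ``value`` of ``quantity`` to the ``target`` unit.

    The value is assumed to currently be in the *other* unit system:
    converting to mg/dL assumes mmol/L input and vice versa.

    Parameters
    ----------
    value : float or array-like
        Strictly positive measurement(s).
    quantity : {"TC", "HDL", "glucose"}
        Measured quantity (aliases "total_cholesterol", "hdl" accepted).
    target : {"mg/dL", "mmol/L"}
        Unit to convert into.
    """
    key = _ALIASES.get(quantity, quantity)
    if key not in CONVERSION_FACTORS:
        raise ValueError(f"unknown quantity {quantity!r}; expected one of "
                         f"{sorted(CONVERSION_FACTORS)}")
    if target not in VALID_TARGETS:
        raise ValueError(f"unknown target unit {target!r}; expected one of {VALID_TARGETS}")
    factor = CONVERSION_FACTORS[key]
    if target == "mg/dL":
        return value * factor
    return value / factor
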