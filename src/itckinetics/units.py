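"""Unit conventions and the single conversion table.

Canonical internal units, applied throughout the package and converted only at
I/O boundaries:

========================  =========
quantity                  unit
========================  =========
time                      s
differential power        μcal/s
concentration             μM
volume                    μL
molar enthalpy            cal/mol
absorbance                AU
extinction coefficient    M⁻¹ cm⁻¹
========================  =========

Sign convention: the calorimeter's power-compensation signal deflects
*negative* for an exothermic reaction, so an exothermic turnover has negative
power and negative ΔH_app, and reaction rates derived from their ratio come
out positive.
"""

from __future__ import annotations

from .exceptions import ValidationError

# Multiplicative factors into the canonical unit.
TIME_TO_S = {"s": 1.0, "sec": 1.0, "seconds": 1.0, "min": 60.0, "h": 3600.0, "ms": 1e-3}

# 1 W = 1/4.184 cal/s, so 1 μW = 0.2390057 μcal/s.
_UW = 1.0 / 4.184
POWER_TO_UCAL_S = {
    "ucal/s": 1.0,
    "µcal/s": 1.0,
    "mcal/s": 1e3,
    "cal/s": 1e6,
    "ncal/s": 1e-3,
    "uW": _UW,
    "µW": _UW,
    "uJ/s": _UW,
    "mW": _UW * 1e3,
    "nW": _UW * 1e-3,
}

CONC_TO_UM = {"uM": 1.0, "µM": 1.0, "mM": 1e3, "M": 1e6, "nM": 1e-3}

VOLUME_TO_UL = {"uL": 1.0, "µL": 1.0, "mL": 1e3, "L": 1e6, "nL": 1e-3}


def convert(value, unit: str, table: dict, quantity: str):
    """Convert ``value`` in ``unit`` to the canonical unit of ``quantity``."""
    try:
        factor = table[unit]
    except KeyError:
        known = ", ".join(sorted(table))
        raise ValidationError(
            f"unknown {quantity} unit {unit!r}; known units: {known}"
        ) from None
    return value * factor
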