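"""Gravimetric leaf water-status variables.

Equivalent water thickness (EWT) is leaf water mass per unit leaf area,

    EWT = (FW - DW) / A        [g cm^-2]

and fuel moisture content (FMC) is water mass as a fraction of fresh mass,

    FMC = (FW - DW) / FW       [dimensionless fraction]

with FW, DW the fresh and dry leaf mass in grams and A the one-sided leaf
area in cm^2.  FMC is held internally as a fraction in (0, 1); format it as
a percentage only at I/O boundaries.
"""

from __future__ import annotations

import numpy as np


def _validate(fw, dw, area=None) -> None:
    fw = np.asarray(fw, dtype=float)
    dw = np.asarray(dw, dtype=float)
    if not np.all((fw > dw) & (dw > 0)):
        raise ValueError(f"need fresh_weight > dry_weight > 0, got FW={fw}, DW={dw}")
    if area is not None and not np.all(np.asarray(area, dtype=float) > 0):
        raise ValueError(f"leaf area must be positive, got {area}")


def compute_ewt(fw, dw, area):
    """Equivalent water thickness (FW - DW) / A in g cm^-2.

    Accepts scalars or arrays; broadcasting follows numpy rules.
    """
    _validate(fw, dw, area)
    out = (np.asarray(fw, dtype=float) - np.asarray(dw, dtype=float)) / np.asarray(area, dtype=float)
    return float(out) if out.ndim == 0 else out


def compute_fmc(fw, dw):
    """Fuel moisture content (FW - DW) / FW as a fraction in (0, 1).

    Algebraically identical to 1 - DW/FW.  Multiply by 100 for the
    conventional percent presentation.
    """
    _validate(fw, dw)
    fw = np.asarray(fw, dtype=float)
    out = (fw - np.asarray(dw, dtype=float)) / fw
    return float(out) if out.ndim == 0 else out
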