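"""Ten classical fixed-band hyperspectral water indices, plus table assembly.

Each index uses the same predefined wavelengths for every leaf (in contrast
to the adaptive SAIs).  On the 1-nm grid, band means are unweighted
arithmetic means over integer wavelengths with inclusive endpoints.

========== =============================================================
WI         rho900 / rho970
SRWI       rho858 / rho1240
NDWI_1240  (rho860 - rho1240) / (rho860 + rho1240)
RDI        (rho1116 - min rho over [1120, 1150]) / rho1116
RATIO_975  2 * mean rho[960, 990] / (mean rho[920, 940] + mean rho[1090, 1100])
RATIO_1200 2 * mean rho[1180, 1220] / (mean rho[1090, 1110] + mean rho[1265, 1285])
DWI        (y1 - rho970) + (y2 - rho1200), y_i from the 850-1080 nm line
MSI        rho1600 / rho820
NDII       (rho860 - rho1600) / (rho860 + rho1600)
GVMI       ((rho820+0.1) - (rho1600+0.02)) / ((rho820+0.1) + (rho1600+0.02))
========== =============================================================

The DWI baseline y_i is the two-point line through (850, rho850) and
(1080, rho1080) evaluated at x1 = 970 and x2 = 1200 nm: the depth of each
water dip below the dry continuum extrapolated from its flanks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .absorption import DEFAULT_WINDOWS, AbsorptionWindow, compute_sai_family
from .spectra import LeafSample, SpectraError, Spectrum, SpectrumSet, join_samples
from .water import compute_ewt, compute_fmc

logger = logging.getLogger(__name__)

CLASSIC_INDEX_NAMES = [
    "WI", "SRWI", "NDWI_1240", "RDI", "RATIO_975", "RATIO_1200",
    "DWI", "MSI", "NDII", "GVMI",
]
SAI_INDEX_NAMES = ["SAI_970", "SAI_1200", "SAI_1660"]
ALL_INDEX_NAMES = SAI_INDEX_NAMES + CLASSIC_INDEX_NAMES

#: stable output column order of the per-sample index table
INDEX_TABLE_COLUMNS = ["sample_id", "species", "ewt", "fmc"] + ALL_INDEX_NAMES

#: RDI minimum search range; the literature also uses [1120, 1250]
RDI_MIN_RANGE = (1120, 1150)


@dataclass(frozen=True)
class ContinuumLine:
    """The dry-continuum line through (850, rho850) and (1080, rho1080)."""

    rho850: float
    rho1080: float

    @property
    def slope(self) -> float:
        return (self.rho1080 - self.rho850) / 230.0

    @property
    def intercept(self) -> float:
        return (self.rho850 * 1080.0 - self.rho1080 * 850.0) / 230.0

    def __call__(self, x_nm: float) -> float:
        return self.slope * x_nm + self.intercept


def compute_classic_indices(s: Spectrum, rdi_min_range: tuple[int, int] = RDI_MIN_RANGE,
                            ) -> dict[str, float]:
    """All ten fixed-band indices for one spectrum.

    An index whose bands the spectrum does not cover comes back NaN with a
    logged reason rather than raising, so partial-coverage spectra still
    yield the indices they can support.
    """
    out: dict[str, float] = {}

    def guard(name: str, fn) -> None:
        try:
            out[name] = float(fn())
        except SpectraError as exc:
            logger.info("%s missing: %s", name, exc)
            out[name] = math.nan

    guard("WI", lambda: s.value_at(900) / s.value_at(970))
    guard("SRWI", lambda: s.value_at(858) / s.value_at(1240))
    guard("NDWI_1240", lambda: (s.value_at(860) - s.value_at(1240))
          / (s.value_at(860) + s.value_at(1240)))

    def _rdi() -> float:
        rho1116 = s.value_at(1116)
        lo, hi = rdi_min_range
        if not s.covers(lo, hi):
            raise SpectraError(f"band [{lo}, {hi}] nm not covered")
        return (rho1116 - s.slice(lo, hi).reflectance.min()) / rho1116

    guard("RDI", _rdi)
    guard("RATIO_975", lambda: 2.0 * s.band_mean(960, 990)
          / (s.band_mean(920, 940) + s.band_mean(1090, 1100)))
    guard("RATIO_1200", lambda: 2.0 * s.band_mean(1180, 1220)
          / (s.band_mean(1090, 1110) + s.band_mean(1265, 1285)))

    def _dwi() -> float:
        line = ContinuumLine(s.value_at(850), s.value_at(1080))
        return (line(970) - s.value_at(970)) + (line(1200) - s.value_at(1200))

    guard("DWI", _dwi)
    guard("MSI", lambda: s.value_at(1600) / s.value_at(820))
    guard("NDII", lambda: (s.value_at(860) - s.value_at(1600))
          / (s.value_at(860) + s.value_at(1600)))
    guard("GVMI", lambda: ((s.value_at(820) + 0.1) - (s.value_at(1600) + 0.02))
          / ((s.value_at(820) + 0.1) + (s.value_at(1600) + 0.02)))
    return out


def build_index_table(spectra: SpectrumSet, metadata: pd.DataFrame,
                      windows: Mapping[str, AbsorptionWindow] | None = None,
                      smooth: bool = True,
                      rdi_min_range: tuple[int, int] = RDI_MIN_RANGE) -> pd.DataFrame:
    """Assemble the per-sample table of all 13 indices plus EWT/FMC.

    One row per sample; missing index values are explicit NaN.  Column
    order is fixed (`INDEX_TABLE_COLUMNS`).
    """
    samples = join_samples(spectra, metadata)
    return index_table_from_samples(samples, windows=windows, smooth=smooth,
                                    rdi_min_range=rdi_min_range)


def index_table_from_samples(samples: Iterable[LeafSample],
                             windows: Mapping[str, AbsorptionWindow] | None = None,
                             smooth: bool = True,
                             rdi_min_range: tuple[int, int] = RDI_MIN_RANGE) -> pd.DataFrame:
    windows = dict(windows) if windows is not None else DEFAULT_WINDOWS
    rows = []
    for sample in samples:
        row: dict[str, object] = {
            "sample_id": sample.sample_id,
            "species": sample.species,
            "ewt": compute_ewt(sample.fresh_weight, sample.dry_weight, sample.area),
            "fmc": compute_fmc(sample.fresh_weight, sample.dry_weight),
        }
        row.update(compute_sai_family(sample.spectrum, windows, smooth=smooth))
        row.update(compute_classic_indices(sample.spectrum, rdi_min_range=rdi_min_range))
        rows.append(row)
    df = pd.DataFrame(rows, columns=INDEX_TABLE_COLUMNS)
    for name in ALL_INDEX_NAMES:
        n_missing = int(df[name].isna().sum()) if len(df) else 0
        if n_missing:
            logger.info("index %s missing for %d/%d samples", name, n_missing, len(df))
    return df
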