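"""Reading, validation, resampling and aggregation of leaf reflectance spectra.

Spectra are reflectance as a function of wavelength (nm) over the 350-2500 nm
range of a field spectroradiometer.  All downstream index computation assumes
a common integer 1-nm grid, which :func:`resample_to_1nm` establishes by
linear interpolation.  Field protocols typically record several readings per
leaf (upper / middle / lower lamina) that are averaged into one spectrum per
sample (:func:`average_replicates`).

Two CSV layouts are accepted:

* ``wide`` — one row per sample, first column ``sample_id``, remaining
  columns named by wavelength in nm (``350``, ``351``, ...).
* ``long`` — columns ``sample_id, wavelength_nm, reflectance``; multiple
  rows for one (sample, wavelength) pair are treated as replicate readings
  and averaged.

Reflectance is expected in [0, 1].  Percent-style files (values up to 100)
are auto-detected and rescaled with a warning.  Values slightly outside
[0, 1] are tolerated with a warning; values outside [-0.05, 1.2] are
rejected as physically impossible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: hard physical bounds — reflectance outside these is an error, not noise
REFLECTANCE_HARD_MIN = -0.05
REFLECTANCE_HARD_MAX = 1.2

#: interior gaps up to this many nm are repaired by linear interpolation
MAX_GAP_NM = 5


class SpectraError(ValueError):
    """Raised for malformed spectra or metadata inputs."""


@dataclass
class Spectrum:
    """One leaf's reflectance sampled on a strictly increasing nm grid."""

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths_nm.ndim != 1 or self.wavelengths_nm.shape != self.reflectance.shape:
            raise SpectraError("wavelengths and reflectance must be 1-D and equal length")
        if len(self.wavelengths_nm) >= 2 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise SpectraError("reflectance contains non-finite values")
        lo, hi = self.reflectance.min(initial=0.0), self.reflectance.max(initial=0.0)
        if lo < REFLECTANCE_HARD_MIN or hi > REFLECTANCE_HARD_MAX:
            raise SpectraError(
                f"reflectance outside physical bounds [{REFLECTANCE_HARD_MIN}, "
                f"{REFLECTANCE_HARD_MAX}]: range [{lo:.4g}, {hi:.4g}]"
            )
        if lo < 0.0 or hi > 1.0:
            logger.warning("reflectance outside [0, 1]: range [%.4g, %.4g]", lo, hi)

    def value_at(self, wavelength_nm: float) -> float:
        """Reflectance at an exact grid wavelength (no interpolation)."""
        idx = np.searchsorted(self.wavelengths_nm, wavelength_nm)
        if idx >= len(self.wavelengths_nm) or self.wavelengths_nm[idx] != wavelength_nm:
            raise SpectraError(f"wavelength {wavelength_nm} nm not on grid")
        return float(self.reflectance[idx])

    def band_mean(self, lo_nm: float, hi_nm: float) -> float:
        """Unweighted mean reflectance over the inclusive band [lo, hi] nm."""
        mask = (self.wavelengths_nm >= lo_nm) & (self.wavelengths_nm <= hi_nm)
        if not mask.any():
            raise SpectraError(f"band [{lo_nm}, {hi_nm}] nm not covered")
        return float(self.reflectance[mask].mean())

    def covers(self, lo_nm: float, hi_nm: float) -> bool:
        return bool(self.wavelengths_nm[0] <= lo_nm and self.wavelengths_nm[-1] >= hi_nm)

    def slice(self, lo_nm: float, hi_nm: float) -> "Spectrum":
        mask = (self.wavelengths_nm >= lo_nm) & (self.wavelengths_nm <= hi_nm)
        return Spectrum(self.wavelengths_nm[mask], self.reflectance[mask])


@dataclass
class LeafSample:
    """A leaf spectrum joined with gravimetric measurements.

    fresh_weight and dry_weight are grams, area is cm^2; these feed the
    equivalent-water-thickness and fuel-moisture-content computations.
    """

    sample_id: str
    species: str
    fresh_weight: float
    dry_weight: float
    area: float
    spectrum: Spectrum

    def __post_init__(self) -> None:
        if not (self.fresh_weight > self.dry_weight > 0):
            raise SpectraError(
                f"sample {self.sample_id}: need fresh_weight > dry_weight > 0, "
                f"got FW={self.fresh_weight}, DW={self.dry_weight}"
            )
        if not self.area > 0:
            raise SpectraError(f"sample {self.sample_id}: area must be positive")


@dataclass
class SpectrumSet:
    """Ordered collection of named spectra sharing one wavelength grid."""

    sample_ids: list[str]
    spectra: list[Spectrum]
    grid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.spectra):
            raise SpectraError("sample_ids and spectra length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise SpectraError(f"duplicate sample ids: {dupes}")
        if self.spectra:
            grid = self.spectra[0].wavelengths_nm
            for sid, s in zip(self.sample_ids, self.spectra):
                if not np.array_equal(s.wavelengths_nm, grid):
                    raise SpectraError(f"sample {sid} is not on the shared grid")
            self.grid = grid
        elif self.grid is None:
            self.grid = np.array([], dtype=float)

    def __len__(self) -> int:
        return len(self.sample_ids)

    def __getitem__(self, sample_id: str) -> Spectrum:
        try:
            return self.spectra[self.sample_ids.index(sample_id)]
        except ValueError:
            raise KeyError(sample_id) from None

    def items(self):
        return zip(self.sample_ids, self.spectra)

    def map(self, fn) -> "SpectrumSet":
        return SpectrumSet(list(self.sample_ids), [fn(s) for s in self.spectra])


def _maybe_rescale_percent(values: np.ndarray) -> np.ndarray:
    """Detect percent-style reflectance (max > 1.5) and rescale to fractions."""
    if np.nanmax(values) > 1.5:
        logger.warning("reflectance looks percent-scaled (max=%.3g); dividing by 100",
                       np.nanmax(values))
        return values / 100.0
    return values


def repair_gaps(s: Spectrum, max_gap_nm: float = MAX_GAP_NM, sample_id: str = "?") -> Spectrum:
    """Fill missing interior wavelengths of a nominally 1-nm grid.

    Gaps of at most ``max_gap_nm`` are bridged by linear interpolation;
    a wider gap raises, since interpolating across it could invent or erase
    an absorption feature.
    """
    wl = s.wavelengths_nm
    steps = np.diff(wl)
    if np.all(steps == 1):
        return s
    if np.any(steps > max_gap_nm + 1):
        worst = wl[:-1][np.argmax(steps)]
        raise SpectraError(
            f"sample {sample_id}: gap of {steps.max():.0f} nm after {worst:.0f} nm "
            f"exceeds the {max_gap_nm} nm repair limit"
        )
    grid = np.arange(wl[0], wl[-1] + 1)
    return Spectrum(grid, np.interp(grid, wl, s.reflectance))


def read_spectra(path: str | Path, layout: str = "wide") -> SpectrumSet:
    """Read leaf reflectance spectra from CSV.

    Parameters
    ----------
    path : file path
    layout : {"wide", "long"}
        ``wide``: one row per sample, wavelength-named columns.
        ``long``: columns (sample_id, wavelength_nm, reflectance);
        duplicate (sample, wavelength) rows are averaged as replicates.

    Returns
    -------
    SpectrumSet on the file's native grid (call :func:`resample_to_1nm`
    afterwards if the grid is not already integer 1-nm).
    """
    path = Path(path)
    if layout == "wide":
        df = pd.read_csv(path)
        if df.columns[0].lower() not in ("sample_id", "id", "sample"):
            raise SpectraError(f"wide layout: first column must be sample_id, got {df.columns[0]!r}")
        ids = df.iloc[:, 0].astype(str).tolist()
        try:
            wl = np.array([float(c) for c in df.columns[1:]])
        except ValueError as exc:
            raise SpectraError(f"wide layout: non-numeric wavelength column: {exc}") from exc
        order = np.argsort(wl)
        wl = wl[order]
        if len(np.unique(wl)) != len(wl):
            raise SpectraError("wide layout: duplicate wavelength columns")
        values = df.iloc[:, 1:].to_numpy(dtype=float)[:, order]
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise SpectraError(
                f"non-numeric/missing reflectance for sample {ids[bad[0]]} at {wl[bad[1]]:.0f} nm"
            )
        values = _maybe_rescale_percent(values)
        spectra = [Spectrum(wl.copy(), row) for row in values]
        return SpectrumSet(ids, spectra)

    if layout == "long":
        df = pd.read_csv(path)
        required = {"sample_id", "wavelength_nm", "reflectance"}
        missing = required - set(df.columns)
        if missing:
            raise SpectraError(f"long layout: missing columns {sorted(missing)}")
        bad = pd.to_numeric(df["reflectance"], errors="coerce").isna() & df["reflectance"].notna()
        if bad.any():
            raise SpectraError(f"non-numeric reflectance at row {int(np.flatnonzero(bad)[0])}")
        df = df.astype({"wavelength_nm": float, "reflectance": float})
        # replicate readings at the same wavelength are averaged
        agg = df.groupby(["sample_id", "wavelength_nm"], sort=True)["reflectance"].mean()
        ids, spectra = [], []
        grids = {}
        for sid, grp in agg.groupby(level=0, sort=False):
            wl = grp.index.get_level_values(1).to_numpy()
            refl = _maybe_rescale_percent(grp.to_numpy())
            ids.append(str(sid))
            spectra.append(Spectrum(wl, refl))
            grids[str(sid)] = wl
        ref_wl = grids[ids[0]]
        for sid in ids[1:]:
            if grids[sid].shape != ref_wl.shape or not np.array_equal(grids[sid], ref_wl):
                missing_wl = sorted(set(ref_wl) ^ set(grids[sid]))
                raise SpectraError(
                    f"sample {sid}: wavelength grid differs from sample {ids[0]} "
                    f"(first differing wavelengths: {missing_wl[:3]})"
                )
        return SpectrumSet(ids, spectra)

    raise SpectraError(f"unknown layout {layout!r}; expected 'wide' or 'long'")


def write_spectra(spectra: SpectrumSet, path: str | Path, layout: str = "wide") -> None:
    """Write a SpectrumSet to CSV in the given layout (inverse of read_spectra)."""
    path = Path(path)
    if layout == "wide":
        wl = spectra.grid
        cols = [f"{w:.0f}" if float(w).is_integer() else repr(w) for w in wl]
        df = pd.DataFrame([s.reflectance for s in spectra.spectra], columns=cols)
        df.insert(0, "sample_id", spectra.sample_ids)
        df.to_csv(path, index=False)
    elif layout == "long":
        rows = []
        for sid, s in spectra.items():
            rows.append(pd.DataFrame({
                "sample_id": sid,
                "wavelength_nm": s.wavelengths_nm,
                "reflectance": s.reflectance,
            }))
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    else:
        raise SpectraError(f"unknown layout {layout!r}")


def resample_to_1nm(s: Spectrum) -> Spectrum:
    """Linearly interpolate a spectrum onto the integer 1-nm grid it spans.

    No extrapolation: the output grid runs from ceil(min) to floor(max) nm.
    Already-1-nm input is returned unchanged (idempotent).
    """
    wl = s.wavelengths_nm
    if len(wl) < 2:
        raise SpectraError("resampling needs at least 2 wavelengths")
    if np.all(wl == np.round(wl)) and np.all(np.diff(wl) == 1):
        return s
    lo = int(np.ceil(wl[0]))
    hi = int(np.floor(wl[-1]))
    if hi < lo:
        raise SpectraError("input range spans no integer wavelength")
    grid = np.arange(lo, hi + 1, dtype=float)
    return Spectrum(grid, np.interp(grid, wl, s.reflectance))


def average_replicates(replicates: Sequence[Spectrum] | Iterable[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate readings of one leaf.

    Mirrors the measurement protocol of taking several readings per leaf
    and using their mean as the leaf's spectrum.
    """
    reps = list(replicates)
    if not reps:
        raise SpectraError("need at least one replicate")
    grid = reps[0].wavelengths_nm
    for i, r in enumerate(reps[1:], start=2):
        if not np.array_equal(r.wavelengths_nm, grid):
            raise SpectraError(f"replicate {i} grid differs from replicate 1")
    stacked = np.vstack([r.reflectance for r in reps])
    # math.fsum is exactly rounded, so the mean is bit-identical under any
    # permutation of the replicates
    mean = np.array([math.fsum(col) for col in stacked.T]) / len(reps)
    return Spectrum(grid.copy(), mean)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-leaf gravimetric metadata CSV.

    Requires columns sample_id, species, fresh_weight, dry_weight, area
    (grams, grams, cm^2).  Rows violating FW > DW > 0 or area > 0 raise,
    naming the offending samples.
    """
    df = pd.read_csv(path)
    required = ["sample_id", "species", "fresh_weight", "dry_weight", "area"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SpectraError(f"metadata missing columns {missing}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    for col in ("fresh_weight", "dry_weight", "area"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    bad = df[~((df.fresh_weight > df.dry_weight) & (df.dry_weight > 0) & (df.area > 0))]
    if len(bad):
        raise SpectraError(
            "metadata rows violate FW > DW > 0 and area > 0 for samples: "
            + ", ".join(bad.sample_id.tolist())
        )
    if df.sample_id.duplicated().any():
        dupes = df.sample_id[df.sample_id.duplicated()].unique().tolist()
        raise SpectraError(f"duplicate sample ids in metadata: {dupes}")
    return df[required]


def join_samples(spectra: SpectrumSet, metadata: pd.DataFrame) -> list[LeafSample]:
    """Join a SpectrumSet with metadata rows by sample_id into LeafSamples."""
    meta = metadata.set_index("sample_id")
    unknown = [sid for sid in spectra.sample_ids if sid not in meta.index]
    if unknown:
        raise SpectraError(f"spectra samples missing from metadata: {unknown}")
    samples = []
    for sid, spec in spectra.items():
        row = meta.loc[sid]
        samples.append(LeafSample(
            sample_id=sid,
            species=str(row.species),
            fresh_weight=float(row.fresh_weight),
            dry_weight=float(row.dry_weight),
            area=float(row.area),
            spectrum=spec,
        ))
    return samples
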