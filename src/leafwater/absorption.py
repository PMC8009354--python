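"""Adaptive spectral absorption indices (SAIs) from per-leaf feature geometry.

A leaf water (or dry-matter) absorption feature consists of an absorption
peak m — the reflectance minimum of the feature — flanked by two shoulders
S1 and S2, the local reflectance maxima on either side.  The straight line
from S1 to S2 is the nonabsorption baseline: the reflectance the leaf would
show if the absorber were absent.  The spectral absorption index is the
relative absorption depth

    SAI = rho_M / rho_m,

the baseline reflectance at the peak wavelength divided by the measured
peak reflectance.  With the symmetry parameter

    d = (lambda2 - lambda_m) / (lambda2 - lambda1)

the baseline value at the peak is exactly the shoulder-weighted mean
``d*rho1 + (1-d)*rho2`` (the two-point line evaluated at lambda_m), so

    SAI = (d*rho1 + (1-d)*rho2) / rho_m.

Unlike fixed-band indices, the peak and shoulder wavelengths are located
per leaf by extremum search inside configured windows, which makes the
index robust to the few-nm feature shifts between species and leaves.

Three named features are computed: SAI_970 and SAI_1200 over the 915-1085
and 1085-1265 nm leaf-water features, and SAI_1660 over the narrow
1630-1690 nm dry-matter-related feature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Spectrum

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AbsorptionWindow:
    """One named absorption feature window and its shoulder search ranges.

    ``window`` is the full feature extent [a, b]; shoulders are searched only
    near the edges (left shoulder in [a, a_l], right shoulder in [a_r, b]),
    because the shoulders of leaf water features sit at the window edges while
    the interior belongs to the dip itself.  Ranges are inclusive, in nm.
    """

    name: str
    window: tuple[int, int]
    left_shoulder_search: tuple[int, int]
    right_shoulder_search: tuple[int, int]

    def __post_init__(self) -> None:
        a, b = self.window
        al = self.left_shoulder_search[1]
        ar = self.right_shoulder_search[0]
        if not (a <= self.left_shoulder_search[0] and a < al < ar < b
                and self.right_shoulder_search[1] <= b):
            raise ValueError(f"window {self.name}: search ranges must nest as a < a_l < a_r < b")


#: default feature windows; shoulder sub-ranges take ~25% margins at each edge
DEFAULT_WINDOWS: dict[str, AbsorptionWindow] = {
    "SAI_970": AbsorptionWindow("SAI_970", (915, 1085), (915, 940), (1060, 1085)),
    "SAI_1200": AbsorptionWindow("SAI_1200", (1085, 1265), (1085, 1110), (1240, 1265)),
    "SAI_1660": AbsorptionWindow("SAI_1660", (1630, 1690), (1630, 1645), (1675, 1690)),
}

#: Savitzky-Golay smoothing used for extremum LOCATION only (window nm, polyorder)
SMOOTH_WINDOW_NM = 15
SMOOTH_POLYORDER = 2


@dataclass
class AbsorptionFeature:
    """A located absorption feature and its derived SAI quantities.

    lambda1 < lambda_m < lambda2 are the left shoulder, peak, and right
    shoulder wavelengths; rho* their (unsmoothed) reflectances.  ``valid``
    is False when the window shows no true interior dip, in which case the
    SAI value should be treated as missing downstream.
    """

    name: str
    lambda1: float
    lambda2: float
    lambda_m: float
    rho1: float
    rho2: float
    rho_m: float
    d: float = math.nan
    baseline_at_peak: float = math.nan
    sai: float = math.nan
    valid: bool = True
    reason: str = ""


def _argext_smallest_wl(values: np.ndarray, wavelengths: np.ndarray, kind: str) -> int:
    """Index of extremum; ties resolve to the smallest wavelength."""
    if kind == "max":
        target = values.max()
    else:
        target = values.min()
    # np.flatnonzero preserves wavelength order, so [0] is the smallest wl
    return int(np.flatnonzero(values == target)[0])


def smooth_for_location(s: Spectrum, window_nm: int = SMOOTH_WINDOW_NM,
                        polyorder: int = SMOOTH_POLYORDER) -> Spectrum:
    """Savitzky-Golay smoothed copy, used only to locate extrema.

    Reflectance values reported for located wavelengths are always read
    from the raw spectrum; smoothing only stabilises the argmin/argmax
    against measurement noise.
    """
    n = len(s.reflectance)
    win = min(window_nm, n if n % 2 == 1 else n - 1)
    if win <= polyorder:
        return s
    smoothed = savgol_filter(s.reflectance, window_length=win, polyorder=polyorder)
    return Spectrum(s.wavelengths_nm.copy(), np.clip(smoothed, -0.05, 1.2))


def locate_feature(s: Spectrum, w: AbsorptionWindow, smooth: bool = True) -> AbsorptionFeature:
    """Locate the peak and shoulders of one absorption feature.

    The left shoulder is the reflectance maximum over the left search range,
    the right shoulder the maximum over the right search range, and the peak
    the minimum over the open interval between the shoulders.  Ties resolve
    to the smallest wavelength.  The feature is flagged invalid when the
    interior minimum hugs a shoulder (no true dip), unless the whole window
    is flat, which is the well-defined "no absorption" case (SAI = 1).
    """
    a, b = w.window
    if not s.covers(a, b):
        raise ValueError(
            f"{w.name}: spectrum [{s.wavelengths_nm[0]:.0f}, {s.wavelengths_nm[-1]:.0f}] nm "
            f"does not cover window [{a}, {b}] nm")

    loc = smooth_for_location(s.slice(a, b)) if smooth else s.slice(a, b)

    def _search(lo: float, hi: float, kind: str) -> float:
        mask = (loc.wavelengths_nm >= lo) & (loc.wavelengths_nm <= hi)
        wl = loc.wavelengths_nm[mask]
        idx = _argext_smallest_wl(loc.reflectance[mask], wl, kind)
        return float(wl[idx])

    lam1 = _search(*w.left_shoulder_search, "max")
    lam2 = _search(*w.right_shoulder_search, "max")
    lam_m = _search(lam1 + 1, lam2 - 1, "min")

    window_slice = s.slice(a, b)
    flat = bool(np.ptp(window_slice.reflectance) == 0)
    at_edge = lam_m in (lam1 + 1, lam2 - 1)
    valid = flat or not at_edge
    reason = "" if valid else f"no interior dip: minimum at {lam_m:.0f} nm hugs a shoulder"

    return AbsorptionFeature(
        name=w.name,
        lambda1=lam1, lambda2=lam2, lambda_m=lam_m,
        rho1=s.value_at(lam1), rho2=s.value_at(lam2), rho_m=s.value_at(lam_m),
        valid=valid, reason=reason,
    )


def compute_d(lambda1: float, lambda2: float, lambda_m: float) -> float:
    """Absorption symmetry parameter d = (lambda2 - lambda_m) / (lambda2 - lambda1).

    d weights the shoulder reflectances so that d*rho1 + (1-d)*rho2 is the
    nonabsorption baseline evaluated at the peak wavelength.
    """
    if not (lambda1 < lambda_m < lambda2):
        raise ValueError(
            f"need lambda1 < lambda_m < lambda2, got {lambda1}, {lambda_m}, {lambda2}")
    return (lambda2 - lambda_m) / (lambda2 - lambda1)


def compute_sai(f: AbsorptionFeature) -> AbsorptionFeature:
    """Fill in d, the baseline reflectance at the peak, and the SAI ratio.

    Returns a copy of the feature with ``d``, ``baseline_at_peak`` and
    ``sai`` populated.  SAI > 1 signals real absorption (peak below the
    baseline); a flat window yields exactly 1.
    """
    if not f.rho_m > 0:
        raise ValueError(f"{f.name}: peak reflectance must be positive, got {f.rho_m}")
    d = compute_d(f.lambda1, f.lambda2, f.lambda_m)
    baseline = d * f.rho1 + (1.0 - d) * f.rho2
    return replace(f, d=d, baseline_at_peak=baseline, sai=baseline / f.rho_m)


def compute_sai_family(s: Spectrum, windows: dict[str, AbsorptionWindow] | None = None,
                       smooth: bool = True) -> dict[str, float]:
    """Compute all configured SAIs for one spectrum.

    Invalid features (no interior dip) yield NaN with a logged reason;
    windows not covered by the spectrum likewise yield NaN.
    """
    windows = windows or DEFAULT_WINDOWS
    out: dict[str, float] = {}
    for name, w in windows.items():
        try:
            feature = compute_sai(locate_feature(s, w, smooth=smooth))
        except ValueError as exc:
            logger.info("%s missing: %s", name, exc)
            out[name] = math.nan
            continue
        if not feature.valid:
            logger.info("%s missing: %s", name, feature.reason)
            out[name] = math.nan
        else:
            out[name] = feature.sai
    return out
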