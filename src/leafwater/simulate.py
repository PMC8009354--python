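"""Synthetic leaf reflectance spectra with known water-status ground truth.

The generator produces leaf-like reflectance on the 350-2500 nm 1-nm grid as
a smooth continuum multiplied by Gaussian absorption dips plus i.i.d. noise:

    rho(lam) = C(lam) * (1 - sum_k D_k * exp(-(lam - mu_k)^2 / (2 sigma_k^2))) + eps

* The continuum C rises sigmoidally from ~0.05 to ~0.48 across the 700-760
  nm red edge and declines gently beyond 1300 nm, mimicking the NIR plateau
  of a green leaf.
* Water dips sit at mu = 970, 1200, 1450 and 1950 nm with depths
  proportional to equivalent water thickness: at EWT = 0.010 g cm^-2 the
  depths are 0.06, 0.12, 0.55 and 0.75 (capped at 0.95).
* A dry-matter dip at 1660 nm deepens as fuel moisture content falls:
  D_1660 = 0.08 * (1 - FMC) / 0.40.
* Each sample's dip centres are jittered by Normal(0, jitter) nm — the
  between-leaf spectral heterogeneity that adaptive per-leaf band location
  is designed to absorb — and Normal(0, noise_sd) measurement noise is
  added per wavelength.  The 1200 nm dip is deliberately narrow (sigma =
  12 nm, the sharp core of the feature): a fixed 40-nm band then loses part
  of the shifted core to first order while the adaptive peak search tracks
  it, which is the heterogeneity mechanism the adaptive indices exist for.

Gravimetric metadata (FW, DW, area) is back-solved from the drawn EWT/FMC
so that the water-metric formulas recover the ground truth exactly:
area ~ U[10, 40] cm^2, FW = EWT*area/FMC, DW = FW - EWT*area.

The defaults mimic a pooled three-species broadleaf study: species VJ
(n=46, EWT 0.006-0.010 g cm^-2, FMC 57.4-67.2%), VL (n=66, EWT 0.006-0.013,
FMC 62.6-77.5%), VX (n=180, EWT 0.008-0.016, FMC 45.16-82.72%), jitter
sigma 5 nm, noise sd 0.002 reflectance units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumSet

GRID_NM = np.arange(350, 2501, dtype=float)

#: water dip centres (nm) and widths (nm); depths at the 0.010 g cm^-2 reference EWT
WATER_DIPS = {
    970.0: (35.0, 0.06),
    1200.0: (12.0, 0.12),
    1450.0: (60.0, 0.55),
    1950.0: (90.0, 0.75),
}
REFERENCE_EWT = 0.010   # g cm^-2 at which the depths above apply
MAX_DEPTH = 0.95

#: dry-matter dip: centre, width, depth at FMC such that (1-FMC) = 0.40
DRY_DIP_CENTER = 1660.0
DRY_DIP_SIGMA = 12.0
DRY_DIP_DEPTH_REF = 0.08
DRY_DIP_FMC_SCALE = 0.40


@dataclass(frozen=True)
class SpeciesSpec:
    """Sampling ranges for one species in the generated study."""

    n: int
    ewt_range: tuple[float, float]      # g cm^-2
    fmc_range: tuple[float, float]      # fraction
    jitter_nm: float = 5.0              # sd of per-leaf dip-centre shifts
    continuum_height: float = 0.48      # NIR plateau reflectance

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("species needs n >= 1")
        for name, (lo, hi) in (("ewt", self.ewt_range), ("fmc", self.fmc_range)):
            if not (0 < lo <= hi):
                raise ValueError(f"{name}_range must be positive and ordered, got ({lo}, {hi})")
        if self.fmc_range[1] >= 1:
            raise ValueError("fmc must stay below 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full study design: per-species specs plus shared noise level and seed."""

    species: dict[str, SpeciesSpec] = field(default_factory=lambda: dict(DEFAULT_SPECIES))
    noise_sd: float = 0.002
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return sum(s.n for s in self.species.values())


DEFAULT_SPECIES: dict[str, SpeciesSpec] = {
    "VJ": SpeciesSpec(n=46, ewt_range=(0.006, 0.010), fmc_range=(0.574, 0.672)),
    "VL": SpeciesSpec(n=66, ewt_range=(0.006, 0.013), fmc_range=(0.626, 0.775)),
    "VX": SpeciesSpec(n=180, ewt_range=(0.008, 0.016), fmc_range=(0.4516, 0.8272)),
}


def continuum(wavelengths: np.ndarray, height: float = 0.48) -> np.ndarray:
    """Leaf-like dry continuum: red-edge sigmoid then gentle SWIR decline."""
    lam = np.asarray(wavelengths, dtype=float)
    c = 0.05 + (height - 0.05) / (1.0 + np.exp(-(lam - 730.0) / 8.0))
    decline = np.where(lam > 1300.0, 1.0 - 1e-4 * (lam - 1300.0), 1.0)
    return c * decline


def dip_depths(ewt: float, fmc: float) -> dict[float, float]:
    """Ground-truth Gaussian dip depth per centre for one leaf."""
    depths = {}
    for mu, (_, d_ref) in WATER_DIPS.items():
        depths[mu] = min(d_ref * ewt / REFERENCE_EWT, MAX_DEPTH)
    depths[DRY_DIP_CENTER] = min(
        DRY_DIP_DEPTH_REF * (1.0 - fmc) / DRY_DIP_FMC_SCALE, MAX_DEPTH)
    return depths


def generate_leaf_spectrum(ewt: float, fmc: float, jitter_nm: float = 5.0,
                           noise_sd: float = 0.002,
                           seed: int | np.random.Generator = 0,
                           continuum_height: float = 0.48,
                           ) -> tuple[Spectrum, dict]:
    """One synthetic leaf spectrum plus its ground truth.

    Returns (spectrum, truth) where truth records the drawn EWT/FMC and the
    realised (jittered) centre and depth of every absorption dip.
    """
    if not (ewt >= 0 and 0 <= fmc < 1):
        raise ValueError(f"need ewt >= 0 and 0 <= fmc < 1, got {ewt}, {fmc}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    depths = dip_depths(ewt, fmc)
    sigmas = {mu: s for mu, (s, _) in WATER_DIPS.items()}
    sigmas[DRY_DIP_CENTER] = DRY_DIP_SIGMA

    absorb = np.zeros_like(GRID_NM)
    centers = {}
    for mu in sorted(depths):
        center = mu + (rng.normal(0.0, jitter_nm) if jitter_nm > 0 else 0.0)
        centers[mu] = center
        if depths[mu] > 0:
            absorb += depths[mu] * np.exp(-((GRID_NM - center) ** 2) / (2 * sigmas[mu] ** 2))
    if np.any(absorb >= 1.0):
        raise ValueError("total absorption depth reached 1; reduce dip depths")

    rho = continuum(GRID_NM, continuum_height) * (1.0 - absorb)
    if noise_sd > 0:
        rho = rho + rng.normal(0.0, noise_sd, size=GRID_NM.shape)
    rho = np.clip(rho, 0.001, 1.0)

    truth = {
        "true_ewt": ewt,
        "true_fmc": fmc,
        **{f"center_{int(mu)}": centers[mu] for mu in sorted(centers)},
        **{f"depth_{int(mu)}": depths[mu] for mu in sorted(depths)},
    }
    return Spectrum(GRID_NM.copy(), rho), truth


def generate_dataset(cfg: GeneratorConfig | None = None,
                     ) -> tuple[SpectrumSet, pd.DataFrame, pd.DataFrame]:
    """A full synthetic study: spectra, gravimetric metadata, ground truth.

    EWT and FMC are drawn uniformly within each species' range; FW/DW/area
    are back-solved so the gravimetric formulas reproduce the drawn values
    exactly.  Fully deterministic given ``cfg.seed``.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    ids, spectra, meta_rows, truth_rows = [], [], [], []
    i = 0
    for species_name in sorted(cfg.species):
        spec = cfg.species[species_name]
        for _ in range(spec.n):
            i += 1
            sid = f"{species_name}{i:04d}"
            ewt = rng.uniform(*spec.ewt_range)
            fmc = rng.uniform(*spec.fmc_range)
            area = rng.uniform(10.0, 40.0)
            water_mass = ewt * area          # g, = FW - DW
            fw = water_mass / fmc
            dw = fw - water_mass
            if dw <= 0:
                raise ValueError(f"sample {sid}: back-solve gave DW <= 0 (fmc={fmc})")
            spectrum, truth = generate_leaf_spectrum(
                ewt, fmc, jitter_nm=spec.jitter_nm, noise_sd=cfg.noise_sd,
                seed=rng, continuum_height=spec.continuum_height)
            ids.append(sid)
            spectra.append(spectrum)
            meta_rows.append({"sample_id": sid, "species": species_name,
                              "fresh_weight": fw, "dry_weight": dw, "area": area})
            truth_rows.append({"sample_id": sid, "species": species_name, **truth})

    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    return SpectrumSet(ids, spectra), metadata, truth
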