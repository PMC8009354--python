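"""Shared fixtures: synthetic study data and simple constructed spectra."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import leafwater as lw


@pytest.fixture(scope="session")
def study():
    """Full synthetic study at the default design (n=292, 3 species)."""
    spectra, metadata, truth = lw.generate_dataset(lw.GeneratorConfig(seed=11))
    return spectra, metadata, truth


@pytest.fixture(scope="session")
def index_table(study):
    spectra, metadata, _ = study
    return lw.build_index_table(spectra, metadata)


@pytest.fixture
def small_study():
    """A 15-sample study for fast IO/plumbing tests."""
    cfg = lw.GeneratorConfig(
        species={"VX": lw.SpeciesSpec(n=10, ewt_range=(0.008, 0.016), fmc_range=(0.45, 0.82)),
                 "VJ": lw.SpeciesSpec(n=5, ewt_range=(0.006, 0.010), fmc_range=(0.57, 0.67))},
        noise_sd=0.002, seed=3)
    return lw.generate_dataset(cfg)


def make_flat(level: float = 0.4, lo: int = 350, hi: int = 2500) -> lw.Spectrum:
    wl = np.arange(lo, hi + 1, dtype=float)
    return lw.Spectrum(wl, np.full_like(wl, level))


def make_dip(center: float, depth: float, sigma: float, level: float = 0.4,
             slope: float = 0.0, lo: int = 350, hi: int = 2500) -> lw.Spectrum:
    """Continuum (level + slope*(wl-center)) times a single Gaussian dip."""
    wl = np.arange(lo, hi + 1, dtype=float)
    cont = level + slope * (wl - center)
    refl = cont * (1.0 - depth * np.exp(-((wl - center) ** 2) / (2 * sigma ** 2)))
    return lw.Spectrum(wl, refl)
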