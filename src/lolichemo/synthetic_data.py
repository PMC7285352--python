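"""Synthetic NIR spectra with known ground truth.

Generates powdered-plant-like log(1/R) spectra by Beer–Lambert mixing of
Gaussian absorption bands on top of a smooth baseline, wrapped in the
scatter artifacts typical of diffuse-reflectance measurements:

    spectrum_i(λ) = α_i·[baseline(λ) + Σ_c conc_ic·bands_c(λ)]
                    + β_i + γ_i·(λ − λ_mid)/halfspan + ε(λ)

with a per-sample multiplicative factor α, additive offset β, linear
tilt γ and white measurement noise ε.  Replicates share everything but
ε.  Constituent concentrations are drawn log-uniform over configured
ranges: the default configuration mimics a heterogeneous collection of
endophyte-infected meadow fescue — total loline alkaloids spanning
101–5629 mg·kg⁻¹ split into N-formylloline (NFL, ~73% on average),
N-acetylnorloline (NANL, ~16%) and N-acetylloline (NAL, ~11%), plus an
in-planta mycelium concentration over 0.22–3.97 mg·g⁻¹ coupled to total
lolines through a Gaussian copula targeting Kendall τ = 0.48.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError
from .spectra_io import DEFAULT_GRID, SpectraSet, WavelengthGrid

__all__ = [
    "Band",
    "ConstituentSpec",
    "SyntheticConfig",
    "GroundTruth",
    "default_study_config",
    "generate",
    "inject_outliers",
]

LOLINE_NAMES = ("NAL", "NANL", "NFL")


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: centre/width in nm, amplitude per unit concentration."""

    center_nm: float
    width_nm: float
    amplitude: float

    def profile(self, wl: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((wl - self.center_nm) / self.width_nm) ** 2)


@dataclass(frozen=True)
class ConstituentSpec:
    name: str
    bands: tuple[Band, ...]
    unit: str  # "mg/kg" or "mg/g"

    def signature(self, wl: np.ndarray) -> np.ndarray:
        return sum(b.profile(wl) for b in self.bands)


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything the generator needs; a pure function of this (seed included)."""

    n_samples: int = 190
    seed: int = 0
    grid: WavelengthGrid = DEFAULT_GRID
    # total lolines range, split by Dirichlet shares over (NAL, NANL, NFL)
    total_lolines_range: tuple[float, float] = (101.0, 5629.0)
    loline_shares: tuple[float, float, float] = (0.11, 0.16, 0.73)
    share_concentration: float = 300.0  # Dirichlet precision for the shares
    mycelium_range: tuple[float, float] = (0.22, 3.97)
    mycelium_tau: float = 0.48  # Kendall coupling to total lolines
    constituents: tuple[ConstituentSpec, ...] = (
        ConstituentSpec("NAL", (Band(1166.0, 14.0, 3.0e-4), Band(1694.0, 20.0, 2.2e-4)), "mg/kg"),
        ConstituentSpec("NANL", (Band(1242.0, 16.0, 2.0e-4), Band(1730.0, 22.0, 1.6e-4)), "mg/kg"),
        ConstituentSpec(
            "NFL",
            (Band(1390.0, 18.0, 8.0e-5), Band(1672.0, 20.0, 6.0e-5), Band(1756.0, 24.0, 4.5e-5)),
            "mg/kg",
        ),
        ConstituentSpec("mycelium", (Band(1212.0, 20.0, 0.04), Band(1520.0, 18.0, 0.03)), "mg/g"),
    )
    # smooth dry-plant baseline: polynomial in the scaled axis plus broad water bands
    baseline_poly: tuple[float, ...] = (0.45, 0.12, 0.06)
    baseline_bands: tuple[Band, ...] = (Band(1450.0, 40.0, 0.15), Band(1940.0, 55.0, 0.25))
    scatter_mult_sd: float = 0.15   # lognormal sigma of the multiplicative factor
    scatter_add_sd: float = 0.05    # absorbance units
    scatter_tilt_sd: float = 0.02   # absorbance units across the half-span
    noise_sd: float = 3.0e-4        # white noise per replicate, absorbance units
    reference_noise_cv: float = 0.03  # multiplicative reference-assay error
    replicate_count: int = 3

    def validate(self) -> None:
        if self.n_samples < 1 or self.replicate_count < 1:
            raise DomainError("n_samples and replicate_count must be >= 1")
        for lo, hi in (self.total_lolines_range, self.mycelium_range):
            if not (0 < lo < hi):
                raise DomainError("concentration ranges must be positive and increasing")
        wl = self.grid.values()
        for c in self.constituents:
            for b in c.bands:
                if not (wl[0] <= b.center_nm <= wl[-1]):
                    raise DomainError(f"band at {b.center_nm} nm outside the grid")
        if not math.isclose(sum(self.loline_shares), 1.0, abs_tol=1e-9):
            raise DomainError("loline shares must sum to 1")


@dataclass
class GroundTruth:
    """True (noise-free) concentrations and the generating configuration."""

    true_concentrations: pd.DataFrame  # index sample_id, one column per constituent
    config: SyntheticConfig


def default_study_config(seed: int = 0, n_samples: int = 190) -> SyntheticConfig:
    """The default study-like conditions (see the class defaults)."""
    return SyntheticConfig(n_samples=n_samples, seed=seed)


def _log_uniform(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))


def generate(config: SyntheticConfig) -> tuple[SpectraSet, GroundTruth]:
    """Draw a synthetic dataset; bit-identical for identical configs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    wl = config.grid.values()
    names = [c.name for c in config.constituents]

    # --- concentrations ------------------------------------------------
    # Gaussian copula: total lolines and mycelium share a latent normal
    # with correlation rho = sin(pi*tau/2), then each maps through its
    # log-uniform marginal, preserving the Kendall tau of the latents.
    from scipy.stats import norm

    z_lol = rng.standard_normal(n)
    rho = math.sin(math.pi * config.mycelium_tau / 2.0)
    z_myc = rho * z_lol + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    total = _log_uniform(norm.cdf(z_lol), *config.total_lolines_range)
    mycelium = _log_uniform(norm.cdf(z_myc), *config.mycelium_range)
    shares = rng.dirichlet(
        config.share_concentration * np.asarray(config.loline_shares), size=n
    )
    conc = {name: total * shares[:, i] for i, name in enumerate(LOLINE_NAMES)}
    conc["mycelium"] = mycelium
    lolines_present = [k for k in LOLINE_NAMES if k in names]
    truth = pd.DataFrame(
        {name: conc[name] for name in names},
        index=pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample_id"),
    )
    if lolines_present:
        truth["total_lolines"] = sum(conc[k] for k in lolines_present)

    # --- clean analyte spectra -----------------------------------------
    half = (wl[-1] - wl[0]) / 2.0
    t = (wl - wl.mean()) / half
    baseline = np.polynomial.polynomial.polyval(t, np.asarray(config.baseline_poly))
    baseline = baseline + sum(b.profile(wl) for b in config.baseline_bands)
    clean = np.tile(baseline, (n, 1))
    for spec in config.constituents:
        clean += np.outer(conc[spec.name], spec.signature(wl))

    # --- per-sample scatter, per-replicate noise ------------------------
    alpha = np.exp(config.scatter_mult_sd * rng.standard_normal(n))
    beta = config.scatter_add_sd * rng.standard_normal(n)
    gamma = config.scatter_tilt_sd * rng.standard_normal(n)
    sample_spectra = alpha[:, None] * clean + beta[:, None] + np.outer(gamma, t)

    rep = config.replicate_count
    matrix = np.repeat(sample_spectra, rep, axis=0)
    matrix = matrix + config.noise_sd * rng.standard_normal(matrix.shape)

    # --- reported reference values --------------------------------------
    noise = {
        name: conc[name] * (1.0 + config.reference_noise_cv * rng.standard_normal(n))
        for name in names
        if name != "total_lolines"
    }
    reported = pd.DataFrame(noise, index=truth.index)
    if lolines_present:
        reported["total_lolines"] = sum(reported[k] for k in lolines_present)
    reported = reported.clip(lower=0.0)

    meta = pd.DataFrame(
        {
            "sample_id": np.repeat(truth.index.to_numpy(), rep),
            "replicate": np.tile(np.arange(1, rep + 1), n),
        }
    )
    for col in reported.columns:
        meta[col] = np.repeat(reported[col].to_numpy(), rep)

    spectra = SpectraSet(wavelengths=wl, matrix=matrix, meta=meta)
    return spectra, GroundTruth(true_concentrations=truth, config=config)


def inject_outliers(
    spectra: SpectraSet,
    n_spectral: int = 0,
    n_chemical: int = 0,
    seed: int = 0,
) -> tuple[SpectraSet, dict[str, list]]:
    """Corrupt a few samples to exercise the H and T screens.

    Spectral outliers get a 5–10x amplitude blow-up, a 6–12 nm
    wavelength shift and a spurious narrow band scaled to the spectrum's
    own spread — shape distortions that survive scatter correction.
    Chemical outliers have every reference value displaced upward by 6
    column SDs.  Distinct samples are used for the two kinds.  Returns
    the corrupted set and the injected sample ids per kind.
    """
    n_total = len(np.unique(spectra.sample_ids))
    if n_spectral + n_chemical > n_total:
        raise DomainError("more outliers requested than samples available")
    rng = np.random.default_rng(seed)
    unique_ids = pd.unique(spectra.meta["sample_id"])
    chosen = rng.choice(unique_ids, size=n_spectral + n_chemical, replace=False)
    spectral_ids = list(chosen[:n_spectral])
    chemical_ids = list(chosen[n_spectral:])

    matrix = spectra.matrix.copy()
    meta = spectra.meta.copy()
    wl = spectra.wavelengths
    for sid in spectral_ids:
        rows = np.flatnonzero(spectra.sample_ids == sid)
        factor = rng.uniform(5.0, 10.0)
        shift = int(rng.integers(3, 7)) * (1 if rng.random() < 0.5 else -1)
        center = rng.uniform(wl[0] + 30, wl[-1] - 30)
        band_shape = np.exp(-0.5 * ((wl - center) / 15.0) ** 2)
        for r in rows:
            row = matrix[r]
            shifted = np.roll(row, shift)
            if shift > 0:
                shifted[:shift] = row[0]
            else:
                shifted[shift:] = row[-1]
            alien = 2.0 * float(np.std(row, ddof=1)) * band_shape
            matrix[r] = factor * shifted + alien
    ref_cols = spectra.reference_columns
    for sid in chemical_ids:
        rows = meta.index[meta["sample_id"] == sid]
        for col in ref_cols:
            sd = float(np.nanstd(meta[col].to_numpy(dtype=float), ddof=1))
            meta.loc[rows, col] = meta.loc[rows, col] + 6.0 * sd

    out = SpectraSet(wavelengths=wl, matrix=matrix, meta=meta)
    return out, {"spectral": spectral_ids, "chemical": chemical_ids}
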