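"""Simplified canopy + atmosphere forward model: traits to TOA radiance.

This module is a deliberately lightweight, fully documented stand-in for the
heavyweight radiative-transfer models normally used to build hybrid-retrieval
training sets (a SCOPE-class canopy model coupled to a 6SV-class atmospheric
code).  It preserves the structure of that pipeline — leaf absorptance from
pigment/water/dry-matter content, a two-stream-flavoured canopy reflectance
with a soil background, and a Lambertian top-of-atmosphere coupling through
path reflectance, two-way transmittance and spherical albedo — while keeping
every term in closed form so tests have exact oracles.

All spectral constants live in :data:`CONSTANTS` under a version tag; the
forward chain is deterministic given (state, constants version).

Spectral conventions: wavelengths in nm on the fine grid from
:mod:`traitgpr.spectral`; radiance in W m⁻² sr⁻¹ µm⁻¹ (OLCI L1B convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spectral import spectral_grid

__all__ = [
    "CONSTANTS",
    "fvc_from_lai",
    "leaf_absorptance",
    "simulate_toc_reflectance",
    "compute_fapar",
    "simulate_atmo_functions",
    "toc_to_toa",
    "solar_irradiance",
]

# Versioned spectral-constants table for the stand-in forward model.
# Specific absorption shapes are Gaussians in wavelength (center/sigma nm,
# amplitude in cm²/µg for pigments, cm⁻¹ for water, cm²/g for dry matter).
CONSTANTS = {
    "version": "1.0",
    # chlorophyll a+b: blue and red absorption peaks
    "cab_peaks": [(450.0, 40.0, 0.025), (670.0, 30.0, 0.040)],
    # carotenoids: blue-green shoulder
    "car_peaks": [(500.0, 40.0, 0.020)],
    # leaf water: NIR band
    "water_peaks": [(940.0, 45.0, 30.0)],
    # dry matter: spectrally flat
    "dm_flat": 40.0,
    # soil line: rho_s = brightness*(c0 + c1*(lambda-400))*(1 - 0.5*SMC/55)
    "soil_c0": 0.30,
    "soil_c1": 0.0005,
    # default nadir extinction coefficient for FVC = 1 - exp(-k*LAI)
    "k_extinction": 0.5,
    # Rayleigh optical thickness tau_R = a * (lambda_um)^-4
    "rayleigh_a": 0.008569,
    # ozone Chappuis-like band: (center, sigma, amplitude per amt-cm)
    "o3_band": (600.0, 80.0, 0.12),
    # water-vapour band: (center, sigma, amplitude per g cm^-2)
    "wv_band": (940.0, 25.0, 0.05),
    # aerosol single-scattering albedo
    "aerosol_ssa": 0.95,
    # solar irradiance: Planck shape temperature (K) and scale at 500 nm
    "solar_T": 5800.0,
    "solar_E500": 1900.0,  # W m^-2 um^-1
}

_DEG = np.pi / 180.0


def _states_frame(state) -> pd.DataFrame:
    """Accept a DataFrame of states or a single dict/Series; return a frame."""
    if isinstance(state, pd.DataFrame):
        return state
    if isinstance(state, (dict, pd.Series)):
        return pd.DataFrame([state])
    raise TypeError(f"state must be DataFrame, Series or dict, got {type(state)}")


def _col(states: pd.DataFrame, name: str) -> np.ndarray:
    return states[name].to_numpy(float)[:, None]


def _gauss_sum(grid: np.ndarray, peaks) -> np.ndarray:
    out = np.zeros_like(grid)
    for center, sigma, amp in peaks:
        out += amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return out


def fvc_from_lai(lai, k: float | None = None):
    """Fractional vegetation cover from LAI via the nadir gap fraction.

    The gap fraction at nadir is P = exp(−k·LAI) (Beer–Lambert); FVC = 1 − P.
    ``k`` defaults to 0.5 (spherical leaf-angle distribution at nadir).
    """
    if k is None:
        k = CONSTANTS["k_extinction"]
    lai = np.asarray(lai, float)
    if k <= 0:
        raise ValueError(f"extinction coefficient k must be > 0, got {k}")
    if (lai < 0).any():
        raise ValueError("LAI must be nonnegative")
    out = 1.0 - np.exp(-k * lai)
    return float(out) if out.ndim == 0 else out


def leaf_absorptance(state, grid: np.ndarray | None = None) -> np.ndarray:
    """Leaf absorptance spectrum a(λ) ∈ [0, 1).

    a(λ) = 1 − exp(−[LCC·k_cab + Cxc·k_car + Cw·k_w + Cdm·k_dm] / N), where
    the specific-absorption shapes k_x(λ) come from :data:`CONSTANTS` and the
    mesophyll structure parameter N dilutes the per-area optical depth.
    """
    if grid is None:
        grid = spectral_grid()
    states = _states_frame(state)
    tau = (
        _col(states, "LCC") * _gauss_sum(grid, CONSTANTS["cab_peaks"])[None, :]
        + _col(states, "Cxc") * _gauss_sum(grid, CONSTANTS["car_peaks"])[None, :]
        + _col(states, "Cw") * _gauss_sum(grid, CONSTANTS["water_peaks"])[None, :]
        + _col(states, "Cdm") * CONSTANTS["dm_flat"]
    )
    a = 1.0 - np.exp(-tau / _col(states, "N"))
    return a[0] if not isinstance(state, pd.DataFrame) else a


def _canopy_extinction(states: pd.DataFrame) -> np.ndarray:
    """Directional extinction k(θs) = (0.5 + 0.2·LIDF)/cos θs, column vector."""
    sza = _col(states, "SZA") * _DEG
    return (0.5 + 0.2 * _col(states, "LIDF")) / np.cos(sza)


def soil_reflectance(state, grid: np.ndarray | None = None) -> np.ndarray:
    """Bare-soil reflectance: brightness-scaled soil line darkened by moisture."""
    if grid is None:
        grid = spectral_grid()
    states = _states_frame(state)
    line = CONSTANTS["soil_c0"] + CONSTANTS["soil_c1"] * (grid - 400.0)
    rho = _col(states, "BSM_brightness") * line[None, :] * (
        1.0 - 0.5 * _col(states, "SMC") / 55.0
    )
    rho = np.clip(rho, 0.0, 1.0)
    return rho[0] if not isinstance(state, pd.DataFrame) else rho


def simulate_toc_reflectance(state, grid: np.ndarray | None = None) -> np.ndarray:
    """Top-of-canopy reflectance spectrum ρ_c(λ) ∈ [0, 1].

    Infinite-canopy reflectance ρ∞ = (1−√(1−ω))/(1+√(1−ω)) with
    single-scattering albedo ω = 1 − a; the finite canopy relaxes from the
    soil background to ρ∞ as exp(−2·k(θs)·LAI):

        ρ_c = ρ∞ + (ρ_s − ρ∞)·exp(−2·k(θs)·LAI)

    At LAI = 0 this is exactly the soil spectrum; for dense canopies it
    converges to ρ∞.
    """
    if grid is None:
        grid = spectral_grid()
    states = _states_frame(state)
    a = leaf_absorptance(states, grid)
    sqrt_a = np.sqrt(a)  # 1 - omega = a
    rho_inf = (1.0 - sqrt_a) / (1.0 + sqrt_a)
    rho_s = soil_reflectance(states, grid)
    atten = np.exp(-2.0 * _canopy_extinction(states) * _col(states, "LAI"))
    # convex form of rho_inf + (rho_s - rho_inf)*atten: exact at both limits
    rho_c = rho_s * atten + rho_inf * (1.0 - atten)
    return rho_c[0] if not isinstance(state, pd.DataFrame) else rho_c


def compute_fapar(state, grid: np.ndarray | None = None):
    """Fraction of absorbed PAR (400–700 nm), instantaneous at overpass.

    FAPAR = (1 − exp(−k(θs)·LAI)) · ā_PAR, the canopy interception fraction
    times the mean leaf absorptance over the PAR window.  Nondecreasing in
    both LAI and LCC.
    """
    if grid is None:
        grid = spectral_grid()
    states = _states_frame(state)
    a = leaf_absorptance(states, grid)
    par = (grid >= 400.0) & (grid <= 700.0)
    a_par = a[:, par].mean(axis=1)
    intercepted = 1.0 - np.exp(
        -(_canopy_extinction(states)[:, 0]) * states["LAI"].to_numpy(float)
    )
    fapar = intercepted * a_par
    return fapar if isinstance(state, pd.DataFrame) else float(fapar[0])


def solar_irradiance(grid: np.ndarray | None = None) -> np.ndarray:
    """Smooth extraterrestrial solar irradiance E0(λ), W m⁻² µm⁻¹.

    A Planck curve at the solar effective temperature, scaled to a fixed
    irradiance at 500 nm.  Smooth by construction — Fraunhofer structure is
    irrelevant for the stand-in and would only add untestable texture.
    """
    if grid is None:
        grid = spectral_grid()
    lam_m = grid * 1e-9
    T = CONSTANTS["solar_T"]
    hc_kT = 6.62607015e-34 * 2.99792458e8 / (1.380649e-23 * T)

    def planck(lam):
        return lam ** -5 / np.expm1(hc_kT / lam)

    return CONSTANTS["solar_E500"] * planck(lam_m) / planck(500e-9)


def _validate_atmosphere(states: pd.DataFrame) -> None:
    for name in ("O3", "CWV", "AOT", "angstrom"):
        if (states[name].to_numpy(float) < 0).any():
            raise ValueError(f"atmosphere variable {name} must be nonnegative")
    g = states["hg_g"].to_numpy(float)
    if ((g < 0) | (g > 1)).any():
        raise ValueError("hg_g asymmetry factor must be in [0, 1]")


def simulate_atmo_functions(
    state,
    grid: np.ndarray | None = None,
    include_rayleigh: bool = True,
) -> dict[str, np.ndarray]:
    """Atmospheric transfer functions for the Lambertian TOA coupling.

    Returns a dict with keys ``rho_path`` (path reflectance), ``T_dn`` and
    ``T_up`` (down-/upward total transmittance), ``S`` (spherical albedo) and
    ``E0`` (solar irradiance).  Physics of the stand-in:

    * Rayleigh optical thickness τ_R(λ) ∝ λ⁻⁴
    * aerosol τ_A(λ) = AOT₅₅₀·(λ/550)^(−α) (Ångström law)
    * ozone and water-vapour Gaussian absorption bands scaled by O₃ and CWV
    * T_dn = exp(−τ_tot/cos θs),  T_up = exp(−τ_tot/cos θv)
    * ρ_path from single scattering with the Rayleigh phase function and a
      Henyey–Greenstein aerosol phase with asymmetry g
    * S = clip(0.92·τ_R + (1−g)·τ_A, 0, 0.5)

    ``include_rayleigh=False`` zeroes molecular scattering (test configs
    exercising the vacuum limit).
    """
    if grid is None:
        grid = spectral_grid()
    states = _states_frame(state)
    _validate_atmosphere(states)
    single = not isinstance(state, pd.DataFrame)

    lam_um = grid / 1000.0
    tau_r = CONSTANTS["rayleigh_a"] * lam_um ** -4
    if not include_rayleigh:
        tau_r = np.zeros_like(tau_r)
    tau_r = np.broadcast_to(tau_r, (len(states), grid.size))

    tau_a = _col(states, "AOT") * (grid[None, :] / 550.0) ** (-_col(states, "angstrom"))
    c, s, amp = CONSTANTS["o3_band"]
    tau_o3 = _col(states, "O3") * amp * np.exp(-0.5 * ((grid[None, :] - c) / s) ** 2)
    c, s, amp = CONSTANTS["wv_band"]
    tau_wv = _col(states, "CWV") * amp * np.exp(-0.5 * ((grid[None, :] - c) / s) ** 2)
    tau_tot = tau_r + tau_a + tau_o3 + tau_wv

    mu_s = np.cos(_col(states, "SZA") * _DEG)
    mu_v = np.cos(_col(states, "OZA") * _DEG)
    T_dn = np.exp(-tau_tot / mu_s)
    T_up = np.exp(-tau_tot / mu_v)

    # single-scattering path reflectance; scattering angle from the
    # sun/view geometry (RAA convention: 180 deg = principal plane)
    raa = _col(states, "RAA") * _DEG
    sin_s = np.sin(_col(states, "SZA") * _DEG)
    sin_v = np.sin(_col(states, "OZA") * _DEG)
    cos_theta = -mu_s * mu_v + sin_s * sin_v * np.cos(raa)
    p_ray = 0.75 * (1.0 + cos_theta ** 2)
    g = _col(states, "hg_g")
    p_hg = (1.0 - g ** 2) / (1.0 + g ** 2 - 2.0 * g * cos_theta) ** 1.5
    rho_path = (
        tau_r * p_ray + CONSTANTS["aerosol_ssa"] * tau_a * p_hg
    ) / (4.0 * mu_s * mu_v)
    rho_path = np.clip(rho_path, 0.0, 1.0)

    S = np.clip(0.92 * tau_r + (1.0 - g) * tau_a, 0.0, 0.5)
    E0 = np.broadcast_to(solar_irradiance(grid), (len(states), grid.size))

    tf = {"rho_path": rho_path, "T_dn": T_dn, "T_up": T_up, "S": S, "E0": E0}
    if single:
        tf = {k: v[0] for k, v in tf.items()}
    return tf


def toc_to_toa(rho_c: np.ndarray, tf: dict[str, np.ndarray], sza) -> np.ndarray:
    """Lambertian coupling of surface reflectance to TOA radiance.

    L(λ) = (E0·cosθs/π) · (ρ_path + T_dn·T_up·ρ_c / (1 − S·ρ_c))

    The 1/(1−S·ρ_c) factor accounts for multiple surface–atmosphere
    reflections; S·ρ_c ≥ 1 is unphysical and raises.
    """
    rho_c = np.asarray(rho_c, float)
    sza = np.asarray(sza, float)
    S = np.asarray(tf["S"], float)
    if (S * rho_c >= 1.0).any():
        raise ValueError("S*rho_c >= 1: multiple-scattering series diverges")
    mu_s = np.cos(sza * _DEG)
    if mu_s.ndim == 1 and rho_c.ndim == 2:
        mu_s = mu_s[:, None]
    surf = tf["T_dn"] * tf["T_up"] * rho_c / (1.0 - S * rho_c)
    return tf["E0"] * mu_s / np.pi * (tf["rho_path"] + surf)
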