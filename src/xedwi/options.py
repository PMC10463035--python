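"""Fit and spectrum configuration shared by the fitting and spectrum modules."""
from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError

#: free-diffusion coefficient of dilute 129Xe in air/N2, cm^2/s
D_FREE_XE = 0.14


@dataclass
class FitOptions:
    """Options for the stretched-exponential fit and the diffusivity spectrum.

    Parameters
    ----------
    d_free
        Upper bound for fitted DDC, cm²·s⁻¹. Default is the free-diffusion
        scale of dilute ¹²⁹Xe in air/N₂ (0.14 cm²·s⁻¹).
    alpha_floor
        Lower bound for the heterogeneity exponent α during optimisation.
    init_alpha
        α initial value; DDC is initialised from the two-point ADC.
    delta_ms
        Diffusion time Δ in ms. Lm_D scales as √Δ, so this is recorded in
        every output sidecar and must be explicit at pipeline level.
    d_min, d_max, n_points
        Log-spaced diffusivity grid for the spectrum p(D), cm²·s⁻¹. The grid
        deliberately extends far beyond the free-diffusion coefficient so the
        spectrum-weighted mean length approximates the untruncated spectral
        moment of the stretched-exponential's diffusivity distribution (the
        heavy right tail carries non-negligible √D weight); truncate at
        ``d_max = 0.14`` to reproduce a strict free-diffusion cutoff instead.
    series_terms
        Truncation order of the alternating series used for the right tail
        of the spectrum density (monitored; see :mod:`xedwi.stable`).
    quant_ddc, quant_alpha
        Quantisation steps for memoised Lm_D map computation.
    """

    d_free: float = D_FREE_XE
    alpha_floor: float = 0.05
    init_alpha: float = 0.9
    max_iter: int = 200
    tol: float = 1e-12
    delta_ms: float = 8.5
    d_min: float = 1e-6
    d_max: float = 1e4
    n_points: int = 1000
    series_terms: int = 100
    quant_ddc: float = 2.5e-4
    quant_alpha: float = 2.5e-3

    def __post_init__(self):
        if not (0 < self.alpha_floor < 1):
            raise ParameterError("alpha_floor must lie in (0, 1)")
        if self.d_free <= 0:
            raise ParameterError("d_free must be positive")
        if self.delta_ms <= 0:
            raise ParameterError("diffusion time delta_ms must be positive")
        if not (0 < self.d_min < self.d_max):
            raise ParameterError("need 0 < d_min < d_max for the spectrum grid")
        if self.n_points < 16:
            raise ParameterError("spectrum grid needs at least 16 points")
        if self.max_iter < 1 or self.series_terms < 10:
            raise ParameterError("max_iter >= 1 and series_terms >= 10 required")
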