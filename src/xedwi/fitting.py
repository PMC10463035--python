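"""Voxel-wise decay-model fitting.

Two models, in the statsmodels style (a model object built from data whose
``fit()`` returns a results object):

* :class:`ADCModel` — the two-point mono-exponential apparent diffusion
  coefficient, ADC = ln(S(0)/S(b₁))/b₁ with b₁ the first non-zero b-value.
  Two unknowns, two points: the log-ratio is the exact least-squares
  solution, so no solver is involved.
* :class:`StretchedExpModel` — per-voxel nonlinear least squares of
  S(b) = S₀·exp(−(b·DDC)^α) to all b-values, with DDC ∈ (0, D_free] and
  α ∈ (0, 1].

The stretched-exponential solver is a Levenberg–Marquardt iteration run
simultaneously over all masked voxels in log-parameter space
(ln S₀, ln DDC, ln α), with per-voxel damping and strict step acceptance
(a step is taken only if it lowers that voxel's SSE, so the final SSE never
exceeds the SSE at the initialisation). Voxels whose unconstrained optimum
has α > 1 are refit with α pinned at 1, the boundary solution of the
constrained problem. Per-voxel fits are independent; results do not depend
on execution order or on which other voxels are in the mask.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DWVolumeSet, ParameterMap
from .errors import ParameterError
from .options import FitOptions

__all__ = ["ADCModel", "ADCResults", "StretchedExpModel", "StretchedExpResults",
           "StretchedExpFit", "estimate_noise_sd"]


def estimate_noise_sd(volume: np.ndarray, corner_frac: float = 0.125) -> float:
    """Background noise SD from the image corners of a magnitude volume.

    The eight corner cubes are assumed signal-free; their magnitude values
    are Rayleigh distributed with mean σ√(π/2), giving σ̂ = mean/√(π/2).
    Returns 0 for a noiseless (identically zero background) volume.
    """
    nx, ny, nz = volume.shape
    k = [max(2, int(round(n * corner_frac))) for n in (nx, ny, nz)]
    sl = [(slice(0, k[i]), slice(-k[i], None)) for i in range(3)]
    patches = [volume[a, b, c] for a in sl[0] for b in sl[1] for c in sl[2]]
    vals = np.concatenate([p.ravel() for p in patches])
    return float(vals.mean() / np.sqrt(np.pi / 2.0))


def _resolve_mask(dw: DWVolumeSet, mask) -> np.ndarray:
    if mask is None:
        mask = dw.data[..., 0] > 0
    mask = np.asarray(mask).astype(bool)
    if mask.shape != dw.shape:
        raise ParameterError(f"mask shape {mask.shape} != volume shape {dw.shape}")
    if not mask.any():
        raise ParameterError("empty mask")
    return mask


# ---------------------------------------------------------------------------
# two-point ADC
# ---------------------------------------------------------------------------

class ADCModel:
    """Two-point mono-exponential ADC model for a DW volume set.

    Voxels with non-physical decay (S(b₁) > S(0)) or with S(0) at or below
    the noise floor are marked invalid rather than clipped — flooring them
    at ADC = 0 would bias regional means downward asymmetrically. S(b₁) =
    S(0) gives ADC = 0 (valid, counted as a boundary case in QC).
    """

    def __init__(self, dw: DWVolumeSet, mask=None, noise_floor: float | None = None):
        if dw.n_b < 2:
            raise ParameterError("two-point ADC needs b=0 and at least one positive b-value")
        self.dw = dw
        self.mask = _resolve_mask(dw, mask)
        if noise_floor is None:
            noise_floor = 3.0 * estimate_noise_sd(dw.data[..., 0])
        self.noise_floor = float(noise_floor)

    def fit(self) -> "ADCResults":
        dw = self.dw
        b1 = float(dw.b_values[1])
        s0 = dw.data[..., 0]
        s1 = dw.data[..., 1]
        adc = np.full(dw.shape, np.nan)
        m = self.mask
        below_floor = m & (s0 <= self.noise_floor)
        nonphysical = m & ~below_floor & (s1 > s0)
        zero_s1 = m & ~below_floor & ~nonphysical & (s1 <= 0)
        ok = m & ~below_floor & ~nonphysical & ~zero_s1
        with np.errstate(divide="ignore"):
            adc[ok] = np.log(s0[ok] / s1[ok]) / b1
        qc = {
            "n_masked": int(m.sum()),
            "n_valid": int(ok.sum()),
            "n_below_floor": int(below_floor.sum()),
            "n_nonphysical_decay": int((nonphysical | zero_s1).sum()),
            "n_no_decay": int((ok & (s1 == s0)).sum()),
            "noise_floor": self.noise_floor,
            "b1": b1,
        }
        pmap = ParameterMap(name="ADC", data=adc, affine=dw.affine)
        return ADCResults(model=self, map=pmap, qc=qc)


@dataclass
class ADCResults:
    model: ADCModel
    map: ParameterMap
    qc: dict

    def plot(self, slice_index: int | None = None, **kw):
        from .plotting import plot_map

        return plot_map(self.map, slice_index=slice_index, **kw)

    def summary(self) -> str:
        v = self.map.values()
        lines = [
            "Two-point ADC fit",
            "=" * 40,
            f"b-values used       : 0, {self.qc['b1']:g} s/cm^2",
            f"masked voxels       : {self.qc['n_masked']}",
            f"valid fits          : {self.qc['n_valid']}",
            f"below noise floor   : {self.qc['n_below_floor']}",
            f"non-physical decay  : {self.qc['n_nonphysical_decay']}",
            f"ADC mean (cm^2/s)   : {v.mean():.4f}" if v.size else "ADC mean            : n/a",
            f"ADC median (cm^2/s) : {np.median(v):.4f}" if v.size else "",
        ]
        return "\n".join(filter(None, lines))


# ---------------------------------------------------------------------------
# stretched-exponential fit
# ---------------------------------------------------------------------------

@dataclass
class StretchedExpFit:
    """Diagnostics of a single voxel's stretched-exponential fit."""

    s0: float
    ddc: float
    alpha: float
    rmse: float
    converged: bool
    iterations: int


def _model_and_jac(theta: np.ndarray, b: np.ndarray, want_jac: bool = True):
    """Model f and Jacobian in log-parameters (ln S0, ln DDC, ln alpha).

    With t = (b·D)^α: ∂f/∂lnS0 = f, ∂f/∂lnD = −α·t·f, ∂f/∂lnα = −t·ln(t)·f.
    """
    s0 = np.exp(theta[:, 0:1])
    d = np.exp(theta[:, 1:2])
    a = np.exp(theta[:, 2:3])
    bd = b[None, :] * d
    pos = bd > 0
    t = np.zeros_like(bd)
    t[pos] = np.exp(a.repeat(b.size, 1)[pos] * np.log(bd[pos]))
    f = s0 * np.exp(-t)
    if not want_jac:
        return f, None
    J = np.empty(f.shape + (3,))
    J[..., 0] = f
    J[..., 1] = -a * t * f
    tlnt = np.zeros_like(t)
    pt = t > 0
    tlnt[pt] = t[pt] * np.log(t[pt])
    J[..., 2] = -tlnt * f
    return f, J


def _lm_fit(y: np.ndarray, b: np.ndarray, theta0: np.ndarray, lower: np.ndarray,
            upper: np.ndarray, free: np.ndarray, max_iter: int, tol: float):
    """Vectorised damped least squares over N voxels.

    ``free`` masks the parameters being optimised (fixed ones keep their
    initial value, used for the α = 1 boundary refit). Box bounds are
    enforced by projection before the acceptance test, which preserves the
    descent property. Returns (theta, sse, converged, iterations).
    """
    n = y.shape[0]
    theta = theta0.copy()
    f, _ = _model_and_jac(theta, b, want_jac=False)
    sse = ((y - f) ** 2).sum(axis=1)
    lam = np.full(n, 1e-3)
    converged = np.zeros(n, dtype=bool)
    iters = np.zeros(n, dtype=int)
    idx_free = np.nonzero(free)[0]
    k = idx_free.size
    eye = np.eye(k)
    for _ in range(max_iter):
        active = np.nonzero(~converged)[0]
        if active.size == 0:
            break
        th = theta[active]
        f, J = _model_and_jac(th, b)
        J = J[..., idx_free]
        r = y[active] - f
        A = np.einsum("vbi,vbj->vij", J, J)
        g = np.einsum("vbi,vb->vi", J, r)
        diag = np.maximum(A[:, np.arange(k), np.arange(k)], 1e-12)
        M = A + lam[active, None, None] * diag[:, :, None] * eye[None, :, :]
        try:
            step = np.linalg.solve(M, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.linalg.solve(M + 1e-8 * eye[None], g[..., None])[..., 0]
        trial = th.copy()
        trial[:, idx_free] += step
        np.clip(trial, lower[None, :], upper[None, :], out=trial)
        f_t, _ = _model_and_jac(trial, b, want_jac=False)
        sse_t = ((y[active] - f_t) ** 2).sum(axis=1)
        better = sse_t <= sse[active]
        imp = sse[active] - sse_t
        theta[active[better]] = trial[better]
        sse[active[better]] = sse_t[better]
        lam[active[better]] = np.maximum(lam[active[better]] * 0.3, 1e-12)
        lam[active[~better]] = np.minimum(lam[active[~better]] * 4.0, 1e12)
        iters[active] += 1
        small_step = np.abs(np.where(better[:, None], step, 0.0)).max(axis=1) < 1e-9
        small_imp = better & (imp <= tol * (sse[active] + 1e-300))
        stuck = lam[active] >= 1e12
        converged[active] = (better & small_step) | small_imp | stuck
        # voxels that hit the damping ceiling are *not* flagged converged
        converged[active[stuck & ~(better & small_step) & ~small_imp]] = False
        if np.all(lam[active] >= 1e12):
            break
    return theta, sse, converged, iters


class StretchedExpModel:
    """Stretched-exponential decay model S(b) = S₀·exp(−(b·DDC)^α).

    Requires at least three distinct b-values including 0. Fitting is
    initialised from the two-point ADC (α₀ = 0.9) and bounded to
    DDC ∈ (0, D_free], α ∈ (0, 1]. All-zero or sub-noise-floor voxels are
    flagged invalid rather than raising.
    """

    def __init__(self, dw: DWVolumeSet, mask=None, options: FitOptions | None = None,
                 noise_floor: float | None = None):
        if dw.n_b < 3:
            raise ParameterError("stretched-exponential fit needs >= 3 b-values including 0")
        self.dw = dw
        self.mask = _resolve_mask(dw, mask)
        self.options = options or FitOptions()
        if noise_floor is None:
            noise_floor = 3.0 * estimate_noise_sd(dw.data[..., 0])
        self.noise_floor = float(noise_floor)

    def fit(self) -> "StretchedExpResults":
        dw, opts = self.dw, self.options
        b = dw.b_values
        m = self.mask
        y_all = dw.data[m]                      # (N, nb)
        fit_ok = (y_all[:, 0] > self.noise_floor) & (y_all[:, 0] > 0)
        y = y_all[fit_ok]
        n = y.shape[0]
        b1 = float(b[1])

        # init: two-point ADC (clipped into bounds), alpha0, S0 = S(0)
        with np.errstate(divide="ignore", invalid="ignore"):
            adc2 = np.log(y[:, 0] / np.maximum(y[:, 1], 1e-300)) / b1
        d0 = np.clip(np.nan_to_num(adc2, nan=0.01), 1e-3, opts.d_free)
        theta0 = np.column_stack([np.log(y[:, 0]), np.log(d0),
                                  np.full(n, np.log(opts.init_alpha))])
        lower = np.array([-700.0, np.log(1e-5), np.log(opts.alpha_floor)])
        upper = np.array([700.0, np.log(opts.d_free), np.log(1.5)])
        free = np.array([True, True, True])
        theta, sse, conv, iters = _lm_fit(y, b, theta0, lower, upper, free,
                                          opts.max_iter, opts.tol)

        # α > 1 is outside the model space: the constrained optimum lies on
        # the boundary, so refit those voxels with α pinned at exactly 1
        over = np.exp(theta[:, 2]) > 1.0
        if np.any(over):
            th_b = theta[over].copy()
            th_b[:, 2] = 0.0                    # ln alpha = 0
            upper_b = upper.copy()
            upper_b[2] = 0.0
            th_b2, sse_b, conv_b, it_b = _lm_fit(
                y[over], b, th_b, lower, upper_b,
                np.array([True, True, False]), opts.max_iter, opts.tol)
            theta[over], sse[over] = th_b2, sse_b
            conv[over] = conv_b
            iters[over] += it_b

        s0_v, ddc_v, alpha_v = (np.exp(theta[:, i]) for i in range(3))
        alpha_v = np.minimum(alpha_v, 1.0)
        rmse_v = np.sqrt(sse / b.size)

        def to_map(name, vec):
            full = np.full(dw.shape, np.nan)
            tmp = np.full(fit_ok.size, np.nan)
            tmp[fit_ok] = np.where(conv, vec, np.nan)
            full[m] = tmp
            return ParameterMap(name=name, data=full, affine=dw.affine)

        maps = {
            "S0": to_map("S0", s0_v),
            "DDC": to_map("DDC", ddc_v),
            "alpha": to_map("alpha", alpha_v),
            "rmse": to_map("rmse", rmse_v),
        }
        qc = {
            "n_masked": int(m.sum()),
            "n_below_floor": int((~fit_ok).sum()),
            "n_fitted": int(n),
            "n_converged": int(conv.sum()),
            "n_nonconverged": int((~conv).sum()),
            "n_alpha_at_one": int((alpha_v >= 1.0 - 1e-12).sum()),
            "n_ddc_at_dfree": int((ddc_v >= opts.d_free * (1 - 1e-9)).sum()),
            "noise_floor": self.noise_floor,
            "median_iterations": float(np.median(iters)) if n else float("nan"),
        }
        diag = np.full(fit_ok.size, -1, dtype=int)
        diag[fit_ok] = np.arange(n)
        return StretchedExpResults(
            model=self, maps=maps, qc=qc,
            _mask=m, _diag_index=diag,
            _s0=s0_v, _ddc=ddc_v, _alpha=alpha_v, _rmse=rmse_v,
            _converged=conv, _iterations=iters,
        )


@dataclass
class StretchedExpResults:
    """Results of a voxel-wise stretched-exponential fit.

    ``maps`` holds the S0/DDC/alpha/rmse parameter maps (NaN where invalid);
    :meth:`lmd_map` derives the mean-acinar-dimension map from the
    diffusivity spectrum of each voxel's (DDC, α).
    """

    model: StretchedExpModel
    maps: dict
    qc: dict
    _mask: np.ndarray
    _diag_index: np.ndarray
    _s0: np.ndarray
    _ddc: np.ndarray
    _alpha: np.ndarray
    _rmse: np.ndarray
    _converged: np.ndarray
    _iterations: np.ndarray

    @property
    def s0(self) -> ParameterMap:
        return self.maps["S0"]

    @property
    def ddc(self) -> ParameterMap:
        return self.maps["DDC"]

    @property
    def alpha(self) -> ParameterMap:
        return self.maps["alpha"]

    @property
    def rmse(self) -> ParameterMap:
        return self.maps["rmse"]

    def voxel(self, i: int, j: int, k: int) -> StretchedExpFit:
        """Per-voxel diagnostics; raises KeyError outside the fitted mask."""
        if not self._mask[i, j, k]:
            raise KeyError(f"voxel {(i, j, k)} not in the fitted mask")
        flat = int(np.nonzero(self._mask.ravel())[0].searchsorted(
            np.ravel_multi_index((i, j, k), self._mask.shape)))
        d = self._diag_index[flat]
        if d < 0:
            return StretchedExpFit(np.nan, np.nan, np.nan, np.nan, False, 0)
        return StretchedExpFit(
            s0=float(self._s0[d]), ddc=float(self._ddc[d]), alpha=float(self._alpha[d]),
            rmse=float(self._rmse[d]), converged=bool(self._converged[d]),
            iterations=int(self._iterations[d]),
        )

    def lmd_map(self, delta_ms: float | None = None, memoize: bool = True) -> ParameterMap:
        """Mean acinar dimension map (µm); Δ defaults to the fit options'."""
        from .spectrum import compute_lmd_map

        opts = self.model.options
        if delta_ms is not None and delta_ms != opts.delta_ms:
            from dataclasses import replace
            opts = replace(opts, delta_ms=delta_ms)
        return compute_lmd_map(self.ddc, self.alpha, opts, memoize=memoize)

    def plot(self, name: str = "DDC", slice_index: int | None = None, **kw):
        from .plotting import plot_map

        return plot_map(self.maps[name], slice_index=slice_index, **kw)

    def summary(self) -> str:
        q = self.qc
        rows = [("masked voxels", q["n_masked"]), ("fitted", q["n_fitted"]),
                ("converged", q["n_converged"]), ("non-converged", q["n_nonconverged"]),
                ("below noise floor", q["n_below_floor"]),
                ("alpha at 1 (mono-exp)", q["n_alpha_at_one"]),
                ("DDC at D_free bound", q["n_ddc_at_dfree"])]
        lines = ["Stretched-exponential fit  S(b) = S0 exp(-(b DDC)^alpha)", "=" * 56]
        lines += [f"{k:<26}: {v}" for k, v in rows]
        for name in ("DDC", "alpha"):
            v = self.maps[name].values()
            if v.size:
                lines.append(f"{name + ' median':<26}: {np.median(v):.4g}")
        return "\n".join(lines)
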