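"""Per-voxel apparent diffusion coefficient mapping.

The diffusion-weighted signal at weighting ``b`` (s/mm²) is modelled as
mono-exponential decay, ``S_b = S0 · exp(−b·ADC)``, with ADC in mm²/s.  Each
voxel is fitted independently: a log-linear least-squares fit of ``ln S_b``
against ``b`` gives the starting point, which is then refined by a damped
(Levenberg–Marquardt) nonlinear least-squares minimisation of
``Σ_b (S_b − S0·exp(−b·ADC))²``.  The refinement is run batched across voxels
— the normal equations of the two-parameter model are solved in closed form
per voxel — so whole series fit in seconds.

ADC is carried in mm²/s throughout; the conventional ×10⁻³ display scaling is
applied only when formatting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, EmptyFitError, InvalidGeometryError
from .volumetry import AXIS_ORDER, Mask, _validated_spacing

#: Default 13-point b-value schedule spanning 0–1000 s/mm², densely sampled
#: at low b where the decay is steepest.
DEFAULT_B_VALUES = (0.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0,
                    300.0, 400.0, 500.0, 600.0, 800.0, 1000.0)


@dataclass(frozen=True)
class DwiSeries:
    """A 4D diffusion-weighted stack bound to its b-value schedule.

    ``values`` has shape ``(n_b, slices, rows, columns)``; ``b_values`` must be
    strictly increasing and start at 0.
    """

    values: np.ndarray
    b_values: tuple[float, ...]
    spacing: tuple[float, float, float]
    axis_order: str = AXIS_ORDER

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 4 or arr.size == 0:
            raise InvalidGeometryError(
                f"expected a non-empty 4D stack, got shape {arr.shape}"
            )
        b = tuple(float(x) for x in self.b_values)
        if len(b) != arr.shape[0]:
            raise InvalidGeometryError(
                f"{len(b)} b-values for {arr.shape[0]} volumes"
            )
        if len(b) < 2:
            raise InvalidGeometryError("need at least 2 b-values")
        if b[0] != 0.0:
            raise InvalidGeometryError(f"first b-value must be 0, got {b[0]}")
        if np.any(np.diff(b) <= 0):
            raise InvalidGeometryError(f"b-values must be strictly increasing: {b}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "spacing", _validated_spacing(self.spacing))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:]

    # grid-compatibility duck typing with ImageVolume/Mask
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid_shape


@dataclass(frozen=True)
class AdcMap:
    """Voxelwise fit result: ADC (mm²/s), fitted S0, and diagnostics.

    ``fit_ok`` marks voxels with a converged, unclamped fit from at least two
    positive samples; ``adc`` and ``s0`` are non-negative wherever it is set.
    ``residual_rms`` is NaN on voxels that were never fitted.
    """

    adc: np.ndarray
    s0: np.ndarray
    fit_ok: np.ndarray
    residual_rms: np.ndarray
    spacing: tuple[float, float, float]


def predict_signal(s0, adc, b):
    """Mono-exponential DWI signal ``s0 · exp(−b · adc)`` (broadcasting)."""
    s0 = np.asarray(s0, dtype=float)
    adc = np.asarray(adc, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(s0 < 0) or np.any(adc < 0) or np.any(b < 0):
        raise DomainError("s0, adc and b must all be non-negative")
    out = s0 * np.exp(-b * adc)
    return float(out) if out.ndim == 0 else out


def _loglinear_init(S: np.ndarray, b: np.ndarray):
    """Vectorised log-linear LSQ of ln(S) vs b using positive samples only.

    Returns (s0, adc, n_usable); voxels with < 2 positive samples get NaN.
    """
    pos = S > 0
    n = pos.sum(axis=0).astype(float)
    y = np.where(pos, np.log(np.where(pos, S, 1.0)), 0.0)
    bw = np.where(pos, b[:, None], 0.0)
    sx = bw.sum(axis=0)
    sy = y.sum(axis=0)
    sxx = (bw * bw).sum(axis=0)
    sxy = (bw * y).sum(axis=0)
    den = n * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(den > 0, (n * sxy - sx * sy) / np.where(den > 0, den, 1.0), 0.0)
        intercept = np.where(n > 0, (sy - slope * sx) / np.where(n > 0, n, 1.0), np.nan)
    usable = n >= 2
    s0 = np.where(usable, np.exp(intercept), np.nan)
    adc = np.where(usable, -slope, np.nan)
    return s0, adc, n


def _lm_refine(S, b, s0, adc, max_iter, rtol):
    """Batched damped Gauss–Newton (Levenberg–Marquardt) refinement.

    Operates in place on copies of (s0, adc) for all columns of S; returns the
    refined parameters and a per-voxel convergence flag.
    """
    s0 = s0.copy()
    adc = adc.copy()
    n_vox = S.shape[1]
    lam = np.full(n_vox, 1e-3)
    converged = np.zeros(n_vox, dtype=bool)
    bcol = b[:, None]

    def cost_of(s0_, adc_):
        r = S - s0_ * np.exp(-bcol * adc_)
        return (r * r).sum(axis=0)

    cost = cost_of(s0, adc)
    tiny = np.finfo(float).tiny
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        E = np.exp(-bcol * adc[active])
        r = S[:, active] - s0[active] * E
        J1 = -s0[active] * bcol * E  # d(model)/d(adc); J0 = E
        a00 = (E * E).sum(axis=0)
        a01 = (E * J1).sum(axis=0)
        a11 = (J1 * J1).sum(axis=0)
        g0 = (E * r).sum(axis=0)
        g1 = (J1 * r).sum(axis=0)
        m00 = a00 * (1.0 + lam[active])
        m11 = a11 * (1.0 + lam[active])
        det = m00 * m11 - a01 * a01
        ok = det > tiny
        d0 = np.where(ok, (m11 * g0 - a01 * g1) / np.where(ok, det, 1.0), 0.0)
        d1 = np.where(ok, (m00 * g1 - a01 * g0) / np.where(ok, det, 1.0), 0.0)
        # box the trial point: keep exp(-b*adc) bounded and s0 physical
        s0_try = np.maximum(s0[active] + d0, 0.0)
        adc_try = np.maximum(adc[active] + d1, -1e-2)
        r_try = S[:, active] - s0_try * np.exp(-bcol * adc_try)
        cost_try = (r_try * r_try).sum(axis=0)
        improved = cost_try <= cost[active]

        idx = np.flatnonzero(active)
        acc = idx[improved]
        rej = idx[~improved]
        s0[acc] = s0_try[improved]
        adc[acc] = adc_try[improved]
        cost[acc] = cost_try[improved]
        lam[acc] = np.maximum(lam[acc] / 3.0, 1e-12)
        lam[rej] = np.minimum(lam[rej] * 3.0, 1e8)

        step = np.maximum(
            np.abs(d0[improved]) / (np.abs(s0_try[improved]) + 1e-12),
            np.abs(d1[improved]) / (np.abs(adc_try[improved]) + 1e-12),
        )
        converged[acc[step < rtol]] = True
        # voxels stuck at a singular normal matrix cannot move: stop them
        converged[idx[~ok]] = True
    return s0, adc, converged


def fit_monoexponential(
    series: DwiSeries,
    mask: Mask | None = None,
    *,
    nonlinear: bool = True,
    background_fraction: float = 0.05,
    max_iter: int = 200,
    rtol: float = 1e-8,
) -> AdcMap:
    """Fit ``S_b = S0·exp(−b·ADC)`` per voxel of a DWI series.

    Parameters
    ----------
    series
        The 4D stack and its b-values.
    mask
        Optional region restricting the fit; must share the series grid.
    nonlinear
        Refine the log-linear start with damped nonlinear least squares
        (default).  ``False`` returns the log-linear estimate.
    background_fraction
        Voxels whose measured b=0 signal is below this fraction of the robust
        (99.5th-percentile) maximum are treated as background and left
        unfitted; 0 disables the exclusion.

    Notes
    -----
    Initialisation uses only positive samples; voxels with fewer than two are
    flagged ``fit_ok=False``.  Negative ADC estimates are clamped to 0 and
    flagged.  Raises :class:`EmptyFitError` if no voxel is fittable.
    """
    shape = series.grid_shape
    b = np.asarray(series.b_values, dtype=float)
    S_all = series.values.reshape(len(b), -1).astype(float)

    if mask is not None:
        mask.check_same_grid(series, "DWI series")
        sel = mask.values.ravel().copy()
    else:
        sel = np.ones(S_all.shape[1], dtype=bool)
    if not sel.any():
        raise EmptyFitError("selection mask is empty")

    s_b0 = S_all[0]
    if background_fraction > 0:
        robust_max = np.percentile(s_b0[sel], 99.5)
        sel &= s_b0 >= background_fraction * robust_max
    if not sel.any():
        raise EmptyFitError("every voxel fell below the background threshold")

    S = S_all[:, sel]
    s0_init, adc_init, n_usable = _loglinear_init(S, b)
    usable = n_usable >= 2
    if not usable.any():
        raise EmptyFitError("no voxel has >= 2 positive samples")

    s0_fit = np.where(usable, s0_init, 0.0)
    adc_fit = np.where(usable, adc_init, 0.0)
    if nonlinear:
        s0_u, adc_u, conv = _lm_refine(
            S[:, usable], b, s0_fit[usable], adc_fit[usable], max_iter, rtol
        )
        s0_fit[usable] = s0_u
        adc_fit[usable] = adc_u
        converged = np.zeros_like(usable)
        converged[usable] = conv
    else:
        converged = usable.copy()

    clamped = adc_fit < 0
    adc_fit = np.maximum(adc_fit, 0.0)
    s0_fit = np.maximum(s0_fit, 0.0)
    ok = usable & converged & ~clamped

    resid = S - s0_fit * np.exp(-b[:, None] * adc_fit)
    rms = np.sqrt((resid * resid).mean(axis=0))

    n_total = S_all.shape[1]
    adc_full = np.zeros(n_total)
    s0_full = np.zeros(n_total)
    ok_full = np.zeros(n_total, dtype=bool)
    rms_full = np.full(n_total, np.nan)
    adc_full[sel] = np.where(usable, adc_fit, 0.0)
    s0_full[sel] = np.where(usable, s0_fit, 0.0)
    ok_full[sel] = ok
    rms_full[sel] = np.where(usable, rms, np.nan)

    return AdcMap(
        adc=adc_full.reshape(shape),
        s0=s0_full.reshape(shape),
        fit_ok=ok_full.reshape(shape),
        residual_rms=rms_full.reshape(shape),
        spacing=series.spacing,
    )
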