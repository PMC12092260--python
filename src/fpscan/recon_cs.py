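"""Iterative model-based (compressed-sensing) reconstruction.

For randomly subsampled acquisitions the one-step spectral inversion no
longer applies; the image is instead recovered variationally as

    min_{x >= 0}  1/2 || M A x - y ||^2  +  lambda_eff * TV(x)

where A is the planar forward operator, M the measurement mask over
A-lines, TV the isotropic total-variation seminorm, and
``lambda_eff = lambda * subsampling fraction`` (the regularization
weight is scaled by the fraction of data retained, so the balance
between the shrinking data term and the prior is preserved).

The solver is monotone FISTA: accelerated proximal gradient with step
1/L (L estimated by a seeded power method on A^T M A), the TV+
non-negativity proximal operator computed by a fixed number of inner
dual (fast gradient projection) iterations, and a monotonicity
safeguard that keeps the best iterate so the objective never increases
across outer iterations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .forward_model import PlanarOperator, SensorTimeSeries
from .phantom import PressureVolume
from .units import c_um_per_ns

__all__ = [
    "CSConfig",
    "effective_lambda",
    "tv_seminorm",
    "tv_prox",
    "reconstruct_tv",
]


@dataclass(frozen=True)
class CSConfig:
    """Variational reconstruction parameters.

    ``lambda_tv`` is the regularization weight for a fully sampled
    acquisition (scaled internally by the subsampling fraction); its
    absolute value is implementation-normalized and need not transfer
    between codebases.
    """

    lambda_tv: float = 12e-4
    max_iter: int = 50
    nonneg: bool = True
    subsample_fraction: float = 1.0
    n_inner: int = 10
    n_power_iter: int = 20
    seed: int = 0
    normalize_lambda: bool = True

    def __post_init__(self) -> None:
        if self.lambda_tv < 0:
            raise ValueError("lambda must be non-negative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")


def effective_lambda(base_lambda: float, subsample_fraction: float) -> float:
    """Regularization weight for a subsampled data set:
    lambda_eff = lambda * fraction."""
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must lie in (0, 1]")
    return base_lambda * subsample_fraction


def _gradient(x: np.ndarray) -> tuple[np.ndarray, ...]:
    """Forward differences with Neumann (replicate) boundary."""
    gx = np.zeros_like(x)
    gy = np.zeros_like(x)
    gz = np.zeros_like(x)
    gx[:-1] = x[1:] - x[:-1]
    gy[:, :-1] = x[:, 1:] - x[:, :-1]
    gz[:, :, :-1] = x[:, :, 1:] - x[:, :, :-1]
    return gx, gy, gz


def _grad_adjoint(gx: np.ndarray, gy: np.ndarray, gz: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`_gradient` (negative discrete divergence)."""
    out = np.zeros_like(gx)
    out[:-1] -= gx[:-1]
    out[1:] += gx[:-1]
    out[:, :-1] -= gy[:, :-1]
    out[:, 1:] += gy[:, :-1]
    out[:, :, :-1] -= gz[:, :, :-1]
    out[:, :, 1:] += gz[:, :, :-1]
    return out


def tv_seminorm(vol: PressureVolume | np.ndarray) -> float:
    """Isotropic discrete total variation: sum of voxel gradient
    magnitudes (forward differences, Neumann boundary).  Zero iff the
    volume is constant; positively homogeneous of degree 1."""
    x = vol.p0 if isinstance(vol, PressureVolume) else np.asarray(vol, float)
    gx, gy, gz = _gradient(x)
    return float(np.sum(np.sqrt(gx * gx + gy * gy + gz * gz)))


def tv_prox(
    v: np.ndarray, weight: float, n_iter: int = 10, nonneg: bool = True
) -> np.ndarray:
    """Proximal operator of ``weight * TV + indicator(x >= 0)``.

    Fast gradient projection on the dual (Beck-Teboulle), with the
    non-negativity constraint folded into the primal projection.  A
    fixed, small inner iteration count is used: within an outer
    proximal-gradient loop an inexact prox is sufficient and keeps the
    cost per outer iteration predictable.
    """
    if weight <= 0:
        return np.maximum(v, 0.0) if nonneg else v.copy()

    def project(z):
        return np.maximum(z, 0.0) if nonneg else z

    px = np.zeros_like(v)
    py = np.zeros_like(v)
    pz = np.zeros_like(v)
    qx, qy, qz = px.copy(), py.copy(), pz.copy()
    t = 1.0
    L = 12.0                                   # ||grad^T grad|| bound in 3D
    out = project(v)
    for _ in range(n_iter):
        out = project(v - weight * _grad_adjoint(qx, qy, qz))
        gx, gy, gz = _gradient(out)
        px_n = qx + gx / (L * weight)
        py_n = qy + gy / (L * weight)
        pz_n = qz + gz / (L * weight)
        norm = np.sqrt(px_n**2 + py_n**2 + pz_n**2)
        np.maximum(norm, 1.0, out=norm)
        px_n /= norm
        py_n /= norm
        pz_n /= norm
        t_n = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        a = (t - 1.0) / t_n
        qx = px_n + a * (px_n - px)
        qy = py_n + a * (py_n - py)
        qz = pz_n + a * (pz_n - pz)
        px, py, pz, t = px_n, py_n, pz_n, t_n
    return project(v - weight * _grad_adjoint(px, py, pz))


def reconstruct_tv(
    data: SensorTimeSeries,
    cfg: CSConfig,
    vol_shape: tuple[int, int, int],
    dz_um: float | None = None,
    c_m_s: float | None = None,
    callback=None,
) -> PressureVolume:
    """TV-regularized non-negative least-squares reconstruction.

    Parameters
    ----------
    data:
        Sensor time series; unmeasured A-lines (mask false) are excluded
        from the data term, not treated as zeros.
    cfg:
        Solver configuration.  ``cfg.subsample_fraction`` scales the
        regularization weight via :func:`effective_lambda`.
    vol_shape, dz_um:
        Output grid; ``dz`` defaults to c dt (the native depth sampling).
    c_m_s:
        Sound speed; defaults to the hint carried by the data.

    Returns the non-negative volume after ``cfg.max_iter`` outer
    iterations (initialized at zero).  The recorded objective is
    non-increasing; a sustained increase raises an error naming the
    step size.
    """
    c = c_m_s if c_m_s is not None else data.c_m_s
    dz = dz_um if dz_um is not None else c_um_per_ns(c) * data.dt_ns
    nx, ny, nt = data.p.shape
    if vol_shape[:2] != (nx, ny):
        raise ValueError("volume lateral shape must match the data grid")
    op = PlanarOperator(vol_shape, (data.dx_um, data.dy_um, dz), data.dt_ns,
                        nt, c)
    mask3 = data.mask[:, :, None]
    y = np.where(mask3, data.p, 0.0)
    frac = cfg.subsample_fraction
    # the data term is scaled by 1/fraction so the fixed iteration budget
    # reaches comparable convergence at every subsampling level
    wdat = 1.0 / frac

    lam = effective_lambda(cfg.lambda_tv, frac)
    if cfg.normalize_lambda and lam > 0:
        # make lambda dimensionless relative to the image scale: the
        # sup-norm of the fraction-compensated backprojected data
        nu = float(np.abs(op.adjoint(y)).max()) / frac
        lam *= nu if nu > 0 else 1.0

    # seeded power method for the Lipschitz constant of grad f
    rng = np.random.default_rng(cfg.seed)
    v = rng.standard_normal(vol_shape)
    v /= np.linalg.norm(v)
    L = 1.0
    for _ in range(cfg.n_power_iter):
        w = wdat * op.adjoint(np.where(mask3, op.forward(v), 0.0))
        L = float(np.linalg.norm(w))
        if L == 0:
            L = 1.0
            break
        v = w / L
    step = 1.0 / (1.05 * L)                    # small safety margin

    def objective(x):
        r = np.where(mask3, op.forward(x), 0.0) - y
        return 0.5 * wdat * float(np.sum(r * r)) + wdat * lam * tv_seminorm(x)

    x = np.zeros(vol_shape)
    z = x.copy()
    t = 1.0
    f_best = objective(x)
    x_best = x.copy()
    history = []
    n_bad = 0
    for it in range(cfg.max_iter):
        r = np.where(mask3, op.forward(z), 0.0) - y
        g = wdat * op.adjoint(r)
        xn = z - step * g
        xn = tv_prox(xn, wdat * lam * step, n_iter=cfg.n_inner,
                     nonneg=cfg.nonneg)
        f = objective(xn)
        if f > f_best * (1.0 + 1e-9):
            n_bad += 1
            if n_bad >= 3:
                raise RuntimeError(
                    f"objective diverging for 3 consecutive iterations; "
                    f"step size 1/L = {step:.3e} too large"
                )
            # monotone safeguard: restart momentum from the best iterate
            xn_mono = x_best
        else:
            n_bad = 0
            xn_mono = xn
            f_best = f
            x_best = xn
        t_n = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = xn_mono + ((t - 1.0) / t_n) * (xn_mono - x)
        x, t = xn_mono, t_n
        history.append(f_best)
        if callback is not None:
            res = float(np.sum(r * r))
            callback(it, f_best, res, lam)
    out = PressureVolume(x_best, data.dx_um, data.dy_um, dz)
    out.objective_history = history
    return out
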