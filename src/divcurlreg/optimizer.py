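"""Augmented-Lagrangian registration in div-curl variables.

The registration minimises

    D(F, M, u(f)) + sum_m alpha_m ||grad^sigma_m f1||^2
                  + sum_n beta_n  ||grad^kappa_n (f2, f3, f4)||^2

subject to the solenoidal constraint C(f) = 0, where f are the divergence
and curl channels of the displacement.  Each iteration: reconstruct u from
f (Poisson solves), evaluate the similarity and its gradient, pull the
gradient back to f-space, prune outliers, choose the time step from the
gradient magnitude, take one semi-implicit step per channel (the linear
regulariser solved exactly in a DCT basis, the data and constraint terms
explicit), and update the Lagrange multiplier.  A coarse-to-fine pyramid
wraps the single-level loop.

The semi-implicit step treats the regulariser implicitly, so arbitrarily
high derivative orders cost the same as low ones: the operator is diagonal
in the DCT basis with eigenvalues

    Lambda^rho = (6 - sum_m 2 cos((j_m - 1) pi / n_m))^rho,

the rho-th power of the 7-point negative Laplacian under reflected
(Neumann) boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dctn, idctn
from scipy.ndimage import gaussian_filter, zoom

from .fields import Volume, VectorField, deriv
from .helmholtz import (
    HelmholtzState,
    gradient_pullback,
    inverse_map,
    mean_abs_residual,
    solenoidal_residual,
)
from .similarity import LCCConfig, LCCMetric

log = logging.getLogger(__name__)

__all__ = [
    "RegularizerSpec",
    "SpectralOperator",
    "OptimizerConfig",
    "PyramidConfig",
    "RegistrationResult",
    "RegistrationError",
    "dct_eigenvalues",
    "semi_implicit_update",
    "constraint_force",
    "compute_time_step",
    "prune_outliers",
    "update_multiplier",
    "register_single_level",
    "pyramid_levels",
    "smooth_and_downsample",
    "register",
]

MAX_ORDER = 4  # documented practical cap on derivative orders
_TIME_STEP_CAP = 1e3


class RegistrationError(RuntimeError):
    """Raised when the similarity diverges; carries the diagnostics so far."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass
class RegularizerSpec:
    """Weights and derivative orders of the div and curl penalties.

    ``div_terms`` and ``curl_terms`` are lists of ``(order, weight)`` pairs;
    a single pair per side reproduces the two-weight model with
    ``div_terms=[(sigma, alpha)]`` and ``curl_terms=[(kappa, beta)]``.
    Order 0 penalises the channel amplitude itself (e.g. near-incompressible
    for a strong order-0 div penalty), order 1 its smoothness.
    """

    div_terms: list = field(default_factory=list)
    curl_terms: list = field(default_factory=list)

    def __post_init__(self):
        self.div_terms = [(int(o), float(w)) for o, w in self.div_terms]
        self.curl_terms = [(int(o), float(w)) for o, w in self.curl_terms]
        if not self.div_terms and not self.curl_terms:
            raise ValueError("at least one regularizer term is required")
        for o, w in self.div_terms + self.curl_terms:
            if o < 0 or o > MAX_ORDER:
                raise ValueError(f"derivative order must be in [0, {MAX_ORDER}], got {o}")
            if w < 0:
                raise ValueError(f"weights must be non-negative, got {w}")

    @classmethod
    def from_weights(cls, alpha: float, sigma: int, beta: float, kappa: int):
        """The two-weight model: alpha on grad^sigma div, beta on grad^kappa curl."""
        return cls(div_terms=[(sigma, alpha)], curl_terms=[(kappa, beta)])


@dataclass
class SpectralOperator:
    """Eigenvalue grid of the order-rho regulariser operator in the DCT basis."""

    eigen_grid: np.ndarray
    order: int


@dataclass
class OptimizerConfig:
    """Inner-loop parameters.

    step_prefactor:
        Numerator of the automatic time step; the step is chosen so the
        max-norm of t * (pulled-back gradient) equals this bound.
    theta_factor:
        The penalty weight is tied to the step as theta = theta_factor / t.
    use_alm:
        Disable to run the unconstrained problem (theta = 0, multiplier
        frozen), e.g. for constraint-convergence ablations.
    lam_smooth_sd:
        Gaussian SD (voxels) of the low-pass applied to the multiplier
        after each update.  The multiplier acts on the solution only
        through its gradient, so spatial scales near the grid limit
        accumulate without effect and can grow without bound; restricting
        the multiplier to resolvable scales keeps it bounded and the
        constraint residual at its plateau.  Set to 0 to disable.
    """

    step_prefactor: float = 0.02
    theta_factor: float = 0.4
    iterations_per_level: int = 150
    outlier_sd: float = 3.0
    stop_tol: float = None
    use_alm: bool = True
    lam_smooth_sd: float = 2.0

    def __post_init__(self):
        if self.step_prefactor <= 0 or self.theta_factor < 0:
            raise ValueError("step_prefactor must be > 0 and theta_factor >= 0")
        if self.iterations_per_level < 1 or self.outlier_sd <= 0:
            raise ValueError("iterations_per_level >= 1 and outlier_sd > 0 required")


@dataclass
class PyramidConfig:
    min_dim: int = 16

    def __post_init__(self):
        if self.min_dim < 8:
            raise ValueError("min_dim must be >= 8")


@dataclass
class RegistrationResult:
    displacement: VectorField
    helmholtz: HelmholtzState
    diagnostics: list

    def diagnostics_table(self):
        """Diagnostics as a pandas DataFrame (level, iteration, D, ...)."""
        import pandas as pd

        return pd.DataFrame(self.diagnostics)


def dct_eigenvalues(shape, order: int) -> SpectralOperator:
    """Eigenvalues (6 - sum 2 cos((j-1) pi / n))^order on the DCT-II grid.

    Order 0 yields the identity operator (0^0 := 1).  For order >= 1 the
    (1,1,1) mode (constant field) has eigenvalue 0: pure derivatives do not
    penalise constants.
    """
    if order < 0:
        raise ValueError("order must be a non-negative integer")
    parts = [2.0 * np.cos(np.pi * np.arange(n) / n) for n in shape]
    lam = 6.0 - (
        parts[0][:, None, None] + parts[1][None, :, None] + parts[2][None, None, :]
    )
    if order == 0:
        return SpectralOperator(np.ones(shape), 0)
    return SpectralOperator(lam**order, order)


def _implicit_denominator(shape, terms, t, _cache={}):
    """1 + t * sum_m w_m * Lambda^rho_m, cached per (shape, terms)."""
    denom = np.ones(shape)
    for order, weight in terms:
        key = (shape, order)
        if key not in _cache:
            _cache[key] = dct_eigenvalues(shape, order).eigen_grid
        denom = denom + (t * weight) * _cache[key]
    return denom


def semi_implicit_update(f_channel, explicit_terms, terms, t) -> np.ndarray:
    """One implicit-regulariser step in the DCT basis.

    Computes IDCT{ (1 + t sum w Lambda^rho)^-1 DCT{ f - t * explicit } }
    with orthonormal DCT-II along all axes.  ``terms`` is a list of
    (order, weight) pairs; a single pair gives the two-weight model.
    """
    if t <= 0:
        raise ValueError("time step must be positive")
    x = f_channel - t * explicit_terms
    spec = dctn(x, type=2, norm="ortho")
    spec /= _implicit_denominator(f_channel.shape, tuple(terms), t)
    return idctn(spec, type=2, norm="ortho")


def constraint_force(f: HelmholtzState):
    """Constraint forcing terms for the three curl channels.

    Component i is theta * d C / d x_i + d lam / d x_i.  In the update the
    force enters opposite to the similarity gradient (the step *adds*
    t * force), which diffuses the residual C — one step of the pure
    constraint flow maps C to C + t * theta * lap_w C, where lap_w is the
    wide (stride-2) Laplacian that central differences compose to; its
    spectral radius of 3 keeps the explicit flow stable at the default
    penalty coupling t * theta = 0.4.
    """
    C = solenoidal_residual(f)
    return tuple(f.theta * deriv(C, ax) + deriv(f.lam, ax) for ax in range(3))


def compute_time_step(grads, prefactor: float = 0.02) -> float:
    """Automatic step t = prefactor / max_x ||(dD/df^1..4)(x)||_2.

    Guarantees max-norm of t * gradient <= prefactor exactly.  A vanishing
    gradient (already converged) caps the step at a documented ceiling.
    """
    sq = np.zeros_like(np.asarray(grads[0], dtype=np.float64))
    for g in grads:
        g = np.asarray(g, dtype=np.float64)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite similarity gradient")
        sq += g * g
    gmax = float(np.sqrt(sq.max()))
    if gmax < 1e-12:
        log.warning("vanishing gradient: time step capped at %.0e", _TIME_STEP_CAP)
        return _TIME_STEP_CAP
    return min(prefactor / gmax, _TIME_STEP_CAP)


def prune_outliers(field_values: np.ndarray, k_sd: float = 3.0) -> np.ndarray:
    """Clamp values outside mean +/- k_sd * SD to the nearest in-band value.

    The band is computed once over the whole grid.  A constant field (zero
    SD) is returned unchanged.
    """
    a = np.asarray(field_values, dtype=np.float64)
    mu, sd = float(a.mean()), float(a.std())
    if sd == 0.0:
        return a.copy()
    lo_band, hi_band = mu - k_sd * sd, mu + k_sd * sd
    inband = a[(a >= lo_band) & (a <= hi_band)]
    if inband.size == 0:
        return a.copy()
    return np.clip(a, inband.min(), inband.max())


def update_multiplier(f: HelmholtzState) -> HelmholtzState:
    """First-order ALM multiplier step, lam <- lam + theta * C (in place)."""
    f.lam += f.theta * solenoidal_residual(f)
    return f


def register_single_level(
    F: Volume,
    M: Volume,
    init: HelmholtzState,
    reg: RegularizerSpec,
    cfg: OptimizerConfig = None,
    lcc: LCCConfig = None,
    metric=None,
    mask: np.ndarray = None,
    level: int = 0,
) -> RegistrationResult:
    """The inner ALM loop at a fixed resolution.

    Per iteration: u = inverse_map(f); similarity value/gradient at u;
    pullback to f-space; outlier pruning; automatic t and theta; explicit
    terms (similarity gradient, minus the constraint force on the curl
    channels); one semi-implicit DCT step per channel; multiplier update.
    ``mask`` restricts the diagnostic mean |C| (not the optimisation).
    """
    cfg = cfg if cfg is not None else OptimizerConfig()
    if metric is None:
        metric = LCCMetric(lcc)
    if F.shape != M.shape or F.shape != init.shape:
        raise ValueError("fixed, moving and initial state shapes must match")

    f = init.copy()
    diagnostics = []
    D0 = None
    D_prev = None
    for k in range(cfg.iterations_per_level):
        u = inverse_map(f)
        D, dD_du = metric.value_and_grad(F, M, u)
        if not np.isfinite(D):
            raise RegistrationError(f"similarity diverged (D={D})", diagnostics)
        if D0 is None:
            D0 = D
        elif D > D0 + 10.0 * (abs(D0) + 1e-12):
            raise RegistrationError(
                f"similarity diverged (D={D:.3g} vs initial {D0:.3g})", diagnostics
            )
        grads = [prune_outliers(g, cfg.outlier_sd) for g in gradient_pullback(dD_du)]
        t = compute_time_step(grads, cfg.step_prefactor)
        theta = cfg.theta_factor / t if cfg.use_alm else 0.0
        f.theta = theta

        force = constraint_force(f)
        f.f1 = semi_implicit_update(f.f1, grads[0], reg.div_terms, t)
        new_curl = [
            semi_implicit_update(ch, grads[i + 1] - force[i], reg.curl_terms, t)
            for i, ch in enumerate((f.f2, f.f3, f.f4))
        ]
        f.f2, f.f3, f.f4 = new_curl
        if cfg.use_alm:
            update_multiplier(f)
            if cfg.lam_smooth_sd > 0:
                f.lam = gaussian_filter(f.lam, cfg.lam_smooth_sd)

        gmax4 = np.sqrt(sum(np.asarray(g) ** 2 for g in grads).max())
        diagnostics.append(
            {
                "level": level,
                "iteration": k,
                "D": D,
                "mean_abs_C": mean_abs_residual(f, mask),
                "t": t,
                "theta": theta,
                "max_step": float(t * gmax4),
            }
        )
        if cfg.stop_tol is not None and D_prev is not None:
            if abs(D - D_prev) <= cfg.stop_tol * abs(D_prev):
                break
        D_prev = D

    return RegistrationResult(inverse_map(f), f, diagnostics)


def pyramid_levels(shape, min_dim: int = 16):
    """Descending powers of two [2^L, ..., 2, 1] with every dim / 2^L >= min_dim."""
    if min(shape) < min_dim:
        return [1]
    L = 0
    while all(n // 2 ** (L + 1) >= min_dim for n in shape):
        L += 1
    return [2**l for l in range(L, -1, -1)]


def _resample_to(a: np.ndarray, target_shape) -> np.ndarray:
    if tuple(a.shape) == tuple(target_shape):
        return a.copy()
    factors = [t / n for t, n in zip(target_shape, a.shape)]
    out = zoom(a, factors, order=1, mode="nearest", grid_mode=True)
    assert out.shape == tuple(target_shape)
    return out


def smooth_and_downsample(image: Volume, s: int) -> Volume:
    """Anti-aliased downsampling by factor s: Gaussian SD (s-1)/2, then
    linear resampling.  s = 1 returns the image unchanged (no smoothing)."""
    if s == 1:
        return image
    sd = (s - 1) / 2.0
    sm = gaussian_filter(image.data, sd, mode="nearest")
    target = tuple(max(2, int(round(n / s))) for n in image.shape)
    data = _resample_to(sm, target)
    spacing = tuple(sp * n / t for sp, n, t in zip(image.spacing, image.shape, target))
    return Volume(data, spacing, image.origin)


def register(
    F: Volume,
    M: Volume,
    reg: RegularizerSpec,
    cfg: OptimizerConfig = None,
    lcc: LCCConfig = None,
    pyr: PyramidConfig = None,
    metric=None,
    mask: np.ndarray = None,
) -> RegistrationResult:
    """Coarse-to-fine registration of M onto F.

    Images are smoothed and downsampled per level; the div-curl channels
    and the multiplier are upsampled (linear) to initialise the next finer
    level.  Divergence and curl are voxel-per-voxel derivative quantities,
    so their values transfer across resolutions without rescaling.
    """
    cfg = cfg if cfg is not None else OptimizerConfig()
    pyr = pyr if pyr is not None else PyramidConfig()
    if F.shape != M.shape:
        raise ValueError("fixed and moving shapes must match")

    factors = pyramid_levels(F.shape, pyr.min_dim)
    state = None
    diagnostics = []
    result = None
    for li, s in enumerate(factors):
        Fs = smooth_and_downsample(F, s)
        Ms = smooth_and_downsample(M, s)
        mask_s = None
        if mask is not None:
            mask_s = _resample_to(mask.astype(np.float64), Fs.shape) > 0.5
        if state is None:
            state = HelmholtzState.zeros(Fs.shape)
        else:
            state = HelmholtzState(
                *(_resample_to(ch, Fs.shape) for ch in state.channels),
                lam=_resample_to(state.lam, Fs.shape),
                theta=state.theta,
            )
        if metric is None:
            level_metric = LCCMetric(lcc)
        else:
            level_metric = metric
        result = register_single_level(
            Fs, Ms, state, reg, cfg, lcc, metric=level_metric, mask=mask_s, level=li
        )
        state = result.helmholtz
        diagnostics.extend(result.diagnostics)

    return RegistrationResult(result.displacement, state, diagnostics)
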