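"""Sigmoid models of fin-body coordination.

Larval zebrafish climb by combining two effectors: body rotations in the
pitch axis (posture changes, ``r``, deg) that redirect thrust, and pectoral
fin movements that generate lift, visible as an attack angle (``gamma``,
deg) between swim trajectory and posture at a bout's peak speed.  Attack
angle saturates as a function of posture change and is modelled here with a
logistic function

    gamma(r) = gamma0 + gamma_max / (1 + exp(-k (r - r0)))

where ``gamma0`` is the most negative attack angle, ``gamma0 + gamma_max``
the largest positive attack angle, and ``k`` (1/deg) the steepness.  The
maximal slope of this curve, ``k * gamma_max / 4`` (dimensionless, attained
at ``r = r0``), is the *fin-body ratio*: the amount of fin-driven lift
recruited per degree of body rotation.  The *fin bias*
``slope / (1 + slope)`` maps it into [0, 1).

Because empirical curves at all ages rise from the lower asymptote at
similar posture changes, the centre ``r0`` is parameterised through the
rise position ``r_rise``, the posture change at which the curve reaches 1/8
of its upper asymptote ``gamma0 + gamma_max``.  Solving
``gamma(r_rise) = (gamma0 + gamma_max) / 8`` gives

    r0 = r_rise + (1/k) * ln( 7 (gamma_max + gamma0) / (gamma_max - 7 gamma0) )

Internally the sigmoid is evaluated directly in terms of ``r_rise``,

    gamma(r) = gamma0 + gamma_max / (1 + c * exp(-k (r - r_rise))),
    c = 7 (gamma_max + gamma0) / (gamma_max - 7 gamma0),

which is algebraically identical for k != 0 but remains smooth at k = 0,
keeping unbounded Levenberg-Marquardt fits well behaved when the data carry
no fin-body structure (slope near zero).

A second model, the sum of a sigmoid and its reflection about the vertical
axis,

    gamma_p(r) = gamma(r) + chi * gamma_max / (1 + exp(k (r + r0)))

captures animals (e.g. after cerebellar Purkinje-cell lesion) that pair
positive attack angles with *nose-down* posture changes as well; ``chi``
scales the reflected, nose-down limb.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "POOLED_GAMMA0",
    "POOLED_GAMMA_MAX",
    "POOLED_R_RISE",
    "SigmoidParams",
    "DoubleSigmoidParams",
    "FitResult",
    "eval_sigmoid",
    "eval_double_sigmoid",
    "center_from_rise",
    "fit_sigmoid",
    "fit_double_sigmoid",
    "bootstrap_fit",
    "fin_body_ratio",
    "fin_bias",
]

# Pooled estimates of the three shape parameters, which show no consistent
# developmental trend; one- and two-parameter fits hold them fixed.
POOLED_GAMMA0 = -2.97  # deg, lower asymptote
POOLED_GAMMA_MAX = 17.02  # deg, amplitude (upper asymptote = gamma0 + gamma_max)
POOLED_R_RISE = -1.11  # deg, posture change at 1/8 of the upper asymptote

FitVariant = Literal["four_param", "one_param", "two_param"]


def _rise_constant(gamma0: float, gamma_max: float) -> float:
    """Constant c relating the rise position to the sigmoid centre.

    Requires the 1/8-of-upper-asymptote level to lie strictly between the
    asymptotes, i.e. (gamma0 + gamma_max)/8 in (gamma0, gamma0 + gamma_max).
    """
    num = 7.0 * (gamma_max + gamma0)
    den = gamma_max - 7.0 * gamma0
    if gamma_max <= 0:
        raise ValueError(f"gamma_max must be positive, got {gamma_max}")
    if num <= 0 or den <= 0:
        raise ValueError(
            "1/8-rise level lies outside the open asymptote interval for "
            f"gamma0={gamma0}, gamma_max={gamma_max}"
        )
    return num / den


def center_from_rise(k: float, gamma0: float, gamma_max: float, r_rise: float) -> float:
    """Sigmoid centre r0 such that gamma(r_rise) = (gamma0 + gamma_max)/8.

    Closed form: r0 = r_rise + ln(7 (gamma_max+gamma0) / (gamma_max-7 gamma0)) / k.
    """
    c = _rise_constant(gamma0, gamma_max)
    if k == 0:
        raise ValueError("centre is undefined for a flat sigmoid (k = 0)")
    return r_rise + np.log(c) / k


@dataclass(frozen=True)
class SigmoidParams:
    """Logistic attack-angle model parameters.

    k in 1/deg, angles in deg.  ``r0`` and ``max_slope`` are derived.
    """

    k: float
    gamma0: float = POOLED_GAMMA0
    gamma_max: float = POOLED_GAMMA_MAX
    r_rise: float = POOLED_R_RISE

    def __post_init__(self) -> None:
        _rise_constant(self.gamma0, self.gamma_max)

    @property
    def r0(self) -> float:
        return center_from_rise(self.k, self.gamma0, self.gamma_max, self.r_rise)

    @property
    def max_slope(self) -> float:
        """Fin-body ratio: maximal slope k*gamma_max/4, attained at r0."""
        return self.k * self.gamma_max / 4.0

    def __call__(self, r):
        return eval_sigmoid(self, r)


@dataclass(frozen=True)
class DoubleSigmoidParams:
    """Sum of a sigmoid and its reflection about the vertical axis.

    ``chi`` is the relative amplitude of the reflected (nose-down) limb;
    ``gamma_max`` is fixed at the pooled amplitude by convention.
    """

    chi: float
    k: float
    gamma0: float
    r_rise: float
    gamma_max: float = POOLED_GAMMA_MAX

    def __post_init__(self) -> None:
        _rise_constant(self.gamma0, self.gamma_max)

    @property
    def r0(self) -> float:
        return center_from_rise(self.k, self.gamma0, self.gamma_max, self.r_rise)

    @property
    def nose_up_slope(self) -> float:
        """Maximal slope of the ascending (nose-up) limb, k*gamma_max/4."""
        return self.k * self.gamma_max / 4.0

    @property
    def nose_down_slope(self) -> float:
        """Largest-magnitude slope of the reflected limb, -chi*k*gamma_max/4."""
        return -self.chi * self.k * self.gamma_max / 4.0

    def __call__(self, r):
        return eval_double_sigmoid(self, r)


def _sigmoid(r, k, gamma0, gamma_max, r_rise):
    c = _rise_constant(gamma0, gamma_max)
    with np.errstate(over="ignore"):
        return gamma0 + gamma_max / (1.0 + c * np.exp(-k * (np.asarray(r, float) - r_rise)))


def eval_sigmoid(params: SigmoidParams, r):
    """Evaluate gamma(r) = gamma0 + gamma_max/(1 + exp(-k (r - r0)))."""
    return _sigmoid(r, params.k, params.gamma0, params.gamma_max, params.r_rise)


def eval_double_sigmoid(params: DoubleSigmoidParams, r):
    """Evaluate gamma_p(r) = gamma(r) + chi*gamma_max/(1 + exp(k (r + r0)))."""
    single = _sigmoid(r, params.k, params.gamma0, params.gamma_max, params.r_rise)
    c = _rise_constant(params.gamma0, params.gamma_max)
    with np.errstate(over="ignore"):
        reflected = params.chi * params.gamma_max / (
            1.0 + c * np.exp(params.k * (np.asarray(r, float) + params.r_rise))
        )
    return single + reflected


@dataclass
class FitResult:
    """Least-squares fit of a coordination model to (r, gamma) bout pairs."""

    params: SigmoidParams | DoubleSigmoidParams
    r_squared: float
    n_bouts: int
    variant: str
    fixed_params: tuple[str, ...] = ()
    sse: float = float("nan")
    bootstrap_sd: dict[str, float] | None = None
    slope_ci95: tuple[float, float] | None = None
    n_boot: int = 0
    n_boot_dropped: int = 0

    @property
    def max_slope(self) -> float:
        if isinstance(self.params, DoubleSigmoidParams):
            return self.params.nose_up_slope
        return self.params.max_slope


_MIN_BOUTS = 50

# Initial values for free parameters (Levenberg-Marquardt, no multistart).
_INIT_SINGLE = {"k": 1.0, "gamma0": -0.2, "gamma_max": 20.0, "r_rise": -1.0}
_INIT_DOUBLE = {"chi": 0.5, "k": 1.0, "gamma0": -5.0, "r_rise": 0.0}

_VARIANT_FREE = {
    "four_param": ("k", "gamma0", "gamma_max", "r_rise"),
    "two_param": ("k", "r_rise"),
    "one_param": ("k",),
}


def _clean_pairs(r, gamma):
    r = np.asarray(r, dtype=float).ravel()
    gamma = np.asarray(gamma, dtype=float).ravel()
    if r.shape != gamma.shape:
        raise ValueError("posture-change and attack-angle arrays differ in length")
    ok = np.isfinite(r) & np.isfinite(gamma)
    return r[ok], gamma[ok]


def _r_squared(gamma, pred):
    resid = gamma - pred
    sse = float(resid @ resid)
    sst = float(np.sum((gamma - gamma.mean()) ** 2))
    if sst == 0:
        return (1.0 if sse == 0 else float("-inf")), sse
    return 1.0 - sse / sst, sse


def fit_sigmoid(r, gamma, variant: FitVariant = "four_param",
                min_bouts: int = _MIN_BOUTS) -> FitResult:
    """Fit the logistic coordination model by unbounded Levenberg-Marquardt.

    Variants: ``four_param`` frees (k, gamma0, gamma_max, r_rise);
    ``two_param`` frees (k, r_rise) with the other two fixed at pooled
    means; ``one_param`` frees k only.  Deterministic given data & variant.
    """
    if variant not in _VARIANT_FREE:
        raise ValueError(f"unknown fit variant {variant!r}")
    r, gamma = _clean_pairs(r, gamma)
    if r.size < min_bouts:
        raise ValueError(
            f"need at least {min_bouts} bouts with valid posture change, got {r.size}"
        )
    free = _VARIANT_FREE[variant]
    fixed = {
        "gamma0": POOLED_GAMMA0,
        "gamma_max": POOLED_GAMMA_MAX,
        "r_rise": POOLED_R_RISE,
    }

    def unpack(theta):
        p = dict(fixed)
        p.update(zip(free, theta))
        return p

    def residuals(theta):
        p = unpack(theta)
        try:
            pred = _sigmoid(r, **p)
        except ValueError:
            # asymptote constraint violated mid-search: flat penalty wall
            return np.full_like(gamma, 1e6)
        return pred - gamma

    x0 = np.array([_INIT_SINGLE[name] for name in free])
    sol = least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12,
                        max_nfev=5000)
    if not sol.success:
        raise RuntimeError(
            f"sigmoid fit ({variant}) did not converge: {sol.message}; "
            f"final cost {sol.cost:.4g}, params {unpack(sol.x)}"
        )
    params = SigmoidParams(**unpack(sol.x))
    rsq, sse = _r_squared(gamma, eval_sigmoid(params, r))
    return FitResult(
        params=params,
        r_squared=rsq,
        n_bouts=int(r.size),
        variant=variant,
        fixed_params=tuple(k for k in ("gamma0", "gamma_max", "r_rise") if k not in free),
        sse=sse,
    )


def fit_double_sigmoid(r, gamma, min_bouts: int = _MIN_BOUTS) -> FitResult:
    """Fit the reflected-sum model; amplitude fixed at the pooled gamma_max."""
    r, gamma = _clean_pairs(r, gamma)
    if r.size < min_bouts:
        raise ValueError(
            f"need at least {min_bouts} bouts with valid posture change, got {r.size}"
        )

    def residuals(theta):
        chi, k, gamma0, r_rise = theta
        try:
            params = DoubleSigmoidParams(chi=chi, k=k, gamma0=gamma0, r_rise=r_rise)
        except ValueError:
            return np.full_like(gamma, 1e6)
        return eval_double_sigmoid(params, r) - gamma

    x0 = np.array([_INIT_DOUBLE[n] for n in ("chi", "k", "gamma0", "r_rise")])
    sol = least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12,
                        max_nfev=5000)
    if not sol.success:
        raise RuntimeError(
            f"double-sigmoid fit did not converge: {sol.message}; "
            f"final cost {sol.cost:.4g}"
        )
    params = DoubleSigmoidParams(chi=sol.x[0], k=sol.x[1], gamma0=sol.x[2], r_rise=sol.x[3])
    rsq, sse = _r_squared(gamma, eval_double_sigmoid(params, r))
    return FitResult(
        params=params,
        r_squared=rsq,
        n_bouts=int(r.size),
        variant="double",
        fixed_params=("gamma_max",),
        sse=sse,
    )


def fin_body_ratio(fit: FitResult | SigmoidParams) -> float:
    """Fin-body ratio: the maximal slope k*gamma_max/4 of the fitted sigmoid."""
    params = fit.params if isinstance(fit, FitResult) else fit
    if isinstance(params, DoubleSigmoidParams):
        return params.nose_up_slope
    return params.max_slope


def fin_bias(max_slope: float) -> float:
    """Empirical fin bias slope/(1 + slope), an index in [0, 1).

    Reflects the maximal attack-angle : posture-change ratio of climbing;
    0 = body-only steering, ->1 = fin-dominated steering.
    """
    if max_slope < 0:
        raise ValueError(f"fin bias is defined for non-negative slopes, got {max_slope}")
    return max_slope / (1.0 + max_slope)


def _param_dict(params) -> dict[str, float]:
    if isinstance(params, DoubleSigmoidParams):
        return {"chi": params.chi, "k": params.k, "gamma0": params.gamma0,
                "r_rise": params.r_rise}
    return {"k": params.k, "gamma0": params.gamma0, "gamma_max": params.gamma_max,
            "r_rise": params.r_rise}


def bootstrap_fit(r, gamma, variant: str = "one_param", n_reps: int = 1000,
                  seed: int | None = None, min_bouts: int = _MIN_BOUTS) -> FitResult:
    """Case-resampling bootstrap of a coordination-model fit.

    Resamples bouts with replacement, refits each replicate, and reports
    per-parameter SDs and the 2.5/97.5 percentile CI of the maximal slope.
    Deterministic given ``seed``.  Replicates that fail to converge are
    dropped and counted; more than 10% drops is an error.
    """
    if n_reps < 200:
        raise ValueError(f"bootstrap needs at least 200 replicates, got {n_reps}")
    r, gamma = _clean_pairs(r, gamma)

    def _fit(rr, gg):
        if variant == "double":
            return fit_double_sigmoid(rr, gg, min_bouts=min_bouts)
        return fit_sigmoid(rr, gg, variant=variant, min_bouts=min_bouts)

    point = _fit(r, gamma)
    rng = np.random.default_rng(seed)
    n = r.size
    slopes = []
    param_draws: dict[str, list[float]] = {k: [] for k in _param_dict(point.params)}
    dropped = 0
    for _ in range(n_reps):
        idx = rng.integers(0, n, size=n)
        try:
            rep = _fit(r[idx], gamma[idx])
        except (RuntimeError, ValueError):
            dropped += 1
            continue
        slopes.append(rep.max_slope)
        for name, val in _param_dict(rep.params).items():
            param_draws[name].append(val)
    if dropped > 0.1 * n_reps:
        raise RuntimeError(
            f"bootstrap failed: {dropped}/{n_reps} replicates did not converge"
        )
    slopes_arr = np.asarray(slopes)
    lo, hi = np.percentile(slopes_arr, [2.5, 97.5])
    return replace(
        point,
        bootstrap_sd={k: float(np.std(v, ddof=1)) for k, v in param_draws.items()},
        slope_ci95=(float(lo), float(hi)),
        n_boot=len(slopes),
        n_boot_dropped=dropped,
    )
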