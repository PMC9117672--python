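"""Time- and temperature-dependent birth-death models for a single clade.

Five rate parameterizations are supported, each a speciation rate
lambda(t) and extinction rate mu(t) on the backward time axis (Ma BP):

==========  =============================  ==========================  ===
model id    lambda(t)                      mu(t)                        k
==========  =============================  ==========================  ===
BCST_DCST   lambda0                        mu0                          2
BTEMP_DCST  lambda0 * exp(alpha * T(t))    mu0                          3
BCST_DTEMP  lambda0                        mu0 * exp(beta * T(t))       3
BTIME_DCST  lambda0 * exp(gamma * t)       mu0                          3
BCST_DTIME  lambda0                        mu0 * exp(gamma * t)         3
==========  =============================  ==========================  ===

T(t) is a paleotemperature proxy curve. Because t is measured in Ma BP,
gamma > 0 means a higher rate in the past; the meaning of alpha and beta
depends on the declared proxy orientation.

The log-likelihood integrates, from the tips backward, the extinction
probability E(t) (with E(0) = 1 - f for sampling fraction f) together with
the per-branch survival density D(t); every internal node (the root
included) contributes a factor lambda(t_node), and crown conditioning
divides by lambda(t_crown) * (1 - E(t_crown))^2. Since the single-lineage
D equation is linear given E, the whole-tree likelihood reduces to sums of
the integral Psi(t) = int_0^t [-(lambda+mu) + 2 lambda E] ds evaluated at
the branching times, which is what the compiled kernel returns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._kernels import bd_grid
from .paleo import PaleoCurve
from .trees import Tree

__all__ = [
    "BDModelSpec", "BDFit", "CladeData", "MODEL_IDS",
    "bd_loglik", "fit_bd", "aicdiff",
    "sampling_fraction", "percent_sampled",
]

# model id -> (lambda mode, mu mode, free-parameter names)
# modes: 0 constant, 1 exp(temperature), 2 exp(age)
_MODELS = {
    "BCST_DCST": (0, 0, ("lambda0", "mu0")),
    "BTEMP_DCST": (1, 0, ("lambda0", "alpha", "mu0")),
    "BCST_DTEMP": (0, 1, ("lambda0", "mu0", "beta")),
    "BTIME_DCST": (2, 0, ("lambda0", "gamma", "mu0")),
    "BCST_DTIME": (0, 2, ("lambda0", "mu0", "gamma")),
}
MODEL_IDS = tuple(_MODELS)

_DUMMY_CURVE = (np.array([0.0, 1.0]), np.array([0.0, 0.0]))
_DEFAULT_H = 0.005  # RK4 step, Ma

# rates are optimized in log space; sensitivities on the identity scale
_LOG_PARAMS = {"lambda0", "mu0"}


@dataclass(frozen=True)
class BDModelSpec:
    model_id: str

    def __post_init__(self) -> None:
        if self.model_id not in _MODELS:
            raise ValueError(f"unknown model id {self.model_id!r}; "
                             f"choose from {MODEL_IDS}")

    @property
    def lmode(self) -> int:
        return _MODELS[self.model_id][0]

    @property
    def mmode(self) -> int:
        return _MODELS[self.model_id][1]

    @property
    def param_names(self) -> tuple[str, ...]:
        return _MODELS[self.model_id][2]

    @property
    def k(self) -> int:
        return len(self.param_names)

    @property
    def needs_curve(self) -> bool:
        return 1 in (self.lmode, self.mmode)

    def nested_in(self, other: "BDModelSpec") -> bool:
        """True if this model is a restriction of ``other``."""
        return self.model_id == "BCST_DCST" and other.k > self.k


@dataclass
class CladeData:
    """One clade: a dated tree, its sampling fraction, optionally a curve."""

    tree: Tree
    f: float = 1.0
    curve: PaleoCurve | None = None
    name: str = "clade"

    def __post_init__(self) -> None:
        if not (0.0 < self.f <= 1.0):
            raise ValueError("sampling fraction f must be in (0, 1]")


@dataclass
class BDFit:
    spec: BDModelSpec
    params: dict[str, float]
    lnl: float
    aic: float
    converged: bool
    conditioning: str
    n_starts: int
    seed: int | None
    start_lnls: list[float] = field(default_factory=list)


def sampling_fraction(n_sampled: int, n_known: int) -> float:
    """Sampling fraction f = sampled / known species (e.g. 26/29)."""
    if not (0 < n_sampled <= n_known):
        raise ValueError("need 0 < sampled <= known")
    return n_sampled / n_known


def percent_sampled(n_sampled: int, n_known: int) -> float:
    """Sampling completeness as a whole percentage (e.g. 212/251 -> 84)."""
    return round(100.0 * sampling_fraction(n_sampled, n_known))


def _params_vector(spec: BDModelSpec, params) -> np.ndarray:
    if isinstance(params, dict):
        try:
            return np.array([float(params[p]) for p in spec.param_names])
        except KeyError as exc:
            raise ValueError(f"missing parameter {exc} for {spec.model_id}") from exc
    arr = np.asarray(params, dtype=float)
    if arr.shape != (spec.k,):
        raise ValueError(f"{spec.model_id} expects {spec.k} parameters "
                         f"{spec.param_names}, got shape {arr.shape}")
    return arr


def _unpack(spec: BDModelSpec, vec: np.ndarray):
    names = spec.param_names
    lam0 = vec[list(names).index("lambda0")]
    mu0 = vec[list(names).index("mu0")]
    lcoef = mcoef = 0.0
    if spec.lmode == 1:
        lcoef = vec[list(names).index("alpha")]
    elif spec.lmode == 2:
        lcoef = vec[list(names).index("gamma")]
    if spec.mmode == 1:
        mcoef = vec[list(names).index("beta")]
    elif spec.mmode == 2:
        mcoef = vec[list(names).index("gamma")]
    return lam0, mu0, lcoef, mcoef


def _rate_at(base, mode, coef, curve, t):
    """Vectorized rate evaluation at ages ``t`` (array or scalar)."""
    if mode == 1:
        proxy = (curve.at(t) if curve.interpolation == "spline"
                 else np.interp(t, curve.ages, curve.values))
        return base * np.exp(coef * proxy)
    if mode == 2:
        return base * np.exp(coef * np.asarray(t, dtype=float))
    return base if np.isscalar(t) else np.full(np.shape(t), base)


def bd_loglik(clade: CladeData, spec: BDModelSpec, params,
              conditioning: str = "crown", h: float = _DEFAULT_H) -> float:
    """Log-likelihood of the clade's branching times under the model.

    ``conditioning`` is "crown" (survival of both basal lineages; default)
    or "none". The conditioning choice is a shared constant across compared
    models, so AIC differences are unaffected by it.
    """
    if conditioning not in ("crown", "none"):
        raise ValueError("conditioning must be 'crown' or 'none'")
    vec = _params_vector(spec, params)
    lam0, mu0, _, _ = _unpack(spec, vec)
    if not (lam0 > 0.0) or mu0 < 0.0 or not np.all(np.isfinite(vec)):
        return -np.inf
    if spec.needs_curve and clade.curve is None:
        raise ValueError(f"{spec.model_id} needs a paleotemperature curve")
    lam0, mu0, lcoef, mcoef = _unpack(spec, vec)
    if clade.curve is not None:
        cx, cy = clade.curve.ages, clade.curve.values
    else:
        cx, cy = _DUMMY_CURVE
    bt = clade.tree.branching_times()            # descending, crown first
    ages = np.ascontiguousarray(bt[::-1])        # ascending for the kernel
    E, Psi = bd_grid(ages, lam0, spec.lmode, lcoef, mu0, spec.mmode, mcoef,
                     cx, cy, clade.f, h)
    lam_nodes = np.atleast_1d(_rate_at(lam0, spec.lmode, lcoef,
                                       clade.curve, bt))
    if np.any(lam_nodes <= 0.0):
        return -np.inf
    n = clade.tree.n_tips
    lnl = (n * np.log(clade.f)
           + Psi.sum() + Psi[-1]                # sum over nodes + crown extra
           + np.log(lam_nodes).sum())
    if conditioning == "crown":
        E_crown = E[-1]
        if E_crown >= 1.0:
            return -np.inf
        lnl -= np.log(lam_nodes[0]) + 2.0 * np.log1p(-E_crown)
    return float(lnl)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting (shared machinery, also used by multiclade)
# ---------------------------------------------------------------------------

def _to_internal(spec: BDModelSpec, vec: np.ndarray) -> np.ndarray:
    z = vec.copy()
    for i, name in enumerate(spec.param_names):
        if name in _LOG_PARAMS:
            z[i] = np.log(max(vec[i], 1e-12))
    return z


def _from_internal(spec: BDModelSpec, z: np.ndarray) -> np.ndarray:
    vec = z.copy()
    for i, name in enumerate(spec.param_names):
        if name in _LOG_PARAMS:
            vec[i] = np.exp(z[i])
    return vec


def moment_start(spec: BDModelSpec, n_tips: int, crown_age: float) -> np.ndarray:
    """Method-of-moments style start: net rate from crown-to-present growth."""
    r0 = max(np.log(max(n_tips, 3) / 2.0) / crown_age, 1e-3)
    base = {"lambda0": 1.25 * r0, "mu0": 0.25 * r0,
            "alpha": 0.0, "beta": 0.0, "gamma": 0.0}
    return np.array([base[p] for p in spec.param_names])


def maximize_loglik(spec: BDModelSpec, loglik, start_vec: np.ndarray,
                    n_starts: int = 5, seed: int | None = 0,
                    extra_starts: list[np.ndarray] | None = None):
    """Simplex (Nelder-Mead) maximization in log-rate space, multi-start.

    ``loglik`` maps a natural-scale parameter vector to a log-likelihood.
    Start 1 is ``start_vec`` unjittered; subsequent starts jitter rates by a
    +/-50%-scale lognormal and sensitivities by a small normal. Returns
    (best_vec, best_lnl, converged, start_lnls).
    """
    rng = np.random.default_rng(seed)

    def nobj(z):
        try:
            val = loglik(_from_internal(spec, z))
        except (FloatingPointError, OverflowError):
            return 1e12
        if not np.isfinite(val):
            return 1e12
        return -val

    starts = [start_vec]
    for _ in range(max(n_starts - 1, 0)):
        jit = start_vec.copy()
        for i, name in enumerate(spec.param_names):
            if name in _LOG_PARAMS:
                jit[i] = start_vec[i] * np.exp(rng.normal(0.0, 0.4))
            else:
                jit[i] = start_vec[i] + rng.normal(0.0, 0.05)
        starts.append(jit)
    for es in (extra_starts or []):
        starts.append(np.asarray(es, dtype=float))

    best = None
    start_lnls = []
    any_ok = False
    for s in starts:
        res = minimize(nobj, _to_internal(spec, s), method="Nelder-Mead",
                       options={"maxiter": 400 * spec.k, "xatol": 1e-6,
                                "fatol": 1e-8})
        start_lnls.append(-res.fun)
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    vec = _from_internal(spec, best.x)
    return vec, -best.fun, any_ok, start_lnls


def fit_bd(clade: CladeData, spec: BDModelSpec, *, n_starts: int = 5,
           seed: int | None = 0, conditioning: str = "crown",
           h: float = _DEFAULT_H,
           extra_starts: list[dict] | None = None) -> BDFit:
    """Maximum-likelihood fit of one model to one clade."""
    start = moment_start(spec, clade.tree.n_tips, clade.tree.crown_age)
    extras = [_params_vector(spec, e) for e in (extra_starts or [])]
    vec, lnl, ok, start_lnls = maximize_loglik(
        spec, lambda v: bd_loglik(clade, spec, v, conditioning, h),
        start, n_starts=n_starts, seed=seed, extra_starts=extras)
    params = dict(zip(spec.param_names, (float(v) for v in vec)))
    return BDFit(spec=spec, params=params, lnl=float(lnl),
                 aic=float(-2.0 * lnl + 2.0 * spec.k), converged=ok,
                 conditioning=conditioning, n_starts=n_starts, seed=seed,
                 start_lnls=[float(x) for x in start_lnls])


def aicdiff(null_fit, focal_fit) -> float:
    """AIC(null) - AIC(focal); positive favors the focal model.

    The null must be nested in the focal model with fewer parameters. A
    value of -2 means the focal model's extra parameter bought no
    likelihood; values > 2 are read as substantial support for the focal
    model.
    """
    if not null_fit.spec.nested_in(focal_fit.spec):
        raise ValueError(
            f"{null_fit.spec.model_id} is not nested in {focal_fit.spec.model_id}")
    return float(null_fit.aic - focal_fit.aic)
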