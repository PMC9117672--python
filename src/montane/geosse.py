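"""Generalized multi-region GeoSSE (a ClaSSE parameterization) for n >= 2
regions or two ecological types.

A lineage's state is the non-empty subset of the n regions (or bedrock
types / elevation belts) it occupies, so the state space has 2^n - 1
states; for n = 2 these are the classic GeoSSE endemic-A, endemic-B and
widespread states. The process has

* within-region (constant-state) speciation at rate ``s_i`` for every
  occupied region i, producing daughters ({i}, S);
* state-change (vicariant) speciation of widespread lineages at total rate
  ``s_x``, split uniformly over the 2^(|S|-1) - 1 unordered bipartitions
  of S into two non-empty complementary subsets (for |S| = 2 this is
  exactly GeoSSE's between-region speciation);
* anagenetic range expansion ("migration") from occupied region i into
  unoccupied region j at rate ``d_ij``;
* extirpation of region i at rate ``x_i`` (range contraction for
  widespread lineages, extinction for endemics).

The likelihood is the standard backward ODE system over all states with
per-state extinction probabilities E_S and data partials D_S; tips start
at D = f for the observed state and E = 1 - f everywhere (sampling
fraction applied uniformly across states). Root states are combined by
likelihood-proportional weighting by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd

from ._kernels import classe_prune
from .trees import Tree

__all__ = [
    "states", "GeoSSEParams", "Constraints", "TipStates",
    "SSEFit", "SSEChain",
    "classe_loglik", "fit_sse", "aicdiff_sse", "aicdiff_tests",
    "slice_sample", "mcmc_slice", "asr_marginal", "state_change_proportion",
    "read_tip_states",
]

_DEFAULT_H = 0.01   # RK4 step, Ma
_MAX_REGIONS = 8    # ODE dimension 2*(2^8 - 1) is the practical cap


def states(n: int) -> list[tuple[int, ...]]:
    """The 2^n - 1 non-empty region subsets, by size then lexicographic."""
    if not (1 <= n <= _MAX_REGIONS):
        raise ValueError(f"region count must be in [1, {_MAX_REGIONS}]")
    out: list[tuple[int, ...]] = []
    for size in range(1, n + 1):
        out.extend(combinations(range(n), size))
    return out


@dataclass
class GeoSSEParams:
    """Rates of the n-region model; all non-negative.

    ``d`` is an (n, n) matrix of range-expansion rates from row region into
    column region (diagonal ignored). ``s_x`` is the total state-change
    speciation rate of any widespread lineage.
    """

    n: int
    s: np.ndarray            # within-region speciation, per region
    sx: float                # state-change speciation, total per lineage
    x: np.ndarray            # extirpation/extinction, per region
    d: np.ndarray            # migration (range expansion), (n, n)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.s.shape != (self.n,) or self.x.shape != (self.n,):
            raise ValueError("s and x must have one rate per region")
        if self.d.shape != (self.n, self.n):
            raise ValueError("d must be an (n, n) matrix")
        if (self.s < 0).any() or (self.x < 0).any() or self.sx < 0 \
                or (self.d < 0).any():
            raise ValueError("all rates must be >= 0")

    @classmethod
    def uniform(cls, n: int, s: float, sx: float, x: float, d: float):
        dm = np.full((n, n), d, dtype=float)
        np.fill_diagonal(dm, 0.0)
        return cls(n=n, s=np.full(n, s), sx=sx, x=np.full(n, x), d=dm)

    def permute_regions(self, perm: list[int]) -> "GeoSSEParams":
        """Relabel regions: new region i is old region perm[i]."""
        p = np.asarray(perm)
        return GeoSSEParams(n=self.n, s=self.s[p], sx=self.sx, x=self.x[p],
                            d=self.d[np.ix_(p, p)])


@dataclass(frozen=True)
class Constraints:
    """Named equality/zero constraints defining a model in the family.

    ``d_mode``: "equal" (one rate), "symmetric" (d_ij = d_ji), or "free"
    (directional migration).
    """

    s_equal: bool = True
    sx_zero: bool = False
    x_equal: bool = True
    d_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.d_mode not in ("equal", "symmetric", "free"):
            raise ValueError("d_mode must be 'equal', 'symmetric' or 'free'")

    def param_names(self, n: int) -> list[str]:
        names = ["s"] if self.s_equal else [f"s_{i}" for i in range(n)]
        if not self.sx_zero:
            names.append("sx")
        names += ["x"] if self.x_equal else [f"x_{i}" for i in range(n)]
        if self.d_mode == "equal":
            names.append("d")
        elif self.d_mode == "symmetric":
            names += [f"d_{i}{j}" for i, j in combinations(range(n), 2)]
        else:
            names += [f"d_{i}{j}" for i in range(n) for j in range(n) if i != j]
        return names

    def k(self, n: int) -> int:
        return len(self.param_names(n))

    def nested_in(self, other: "Constraints") -> bool:
        """True if every rate set this family allows is allowed by ``other``."""
        d_order = {"equal": 0, "symmetric": 1, "free": 2}
        return ((self.s_equal or not other.s_equal)
                and (self.x_equal or not other.x_equal)
                and (self.sx_zero or not other.sx_zero)
                and d_order[self.d_mode] <= d_order[other.d_mode])

    def unpack(self, n: int, vec: np.ndarray) -> GeoSSEParams:
        vec = np.asarray(vec, dtype=float)
        i = 0
        if self.s_equal:
            s = np.full(n, vec[i]); i += 1
        else:
            s = vec[i:i + n].copy(); i += n
        if self.sx_zero:
            sx = 0.0
        else:
            sx = float(vec[i]); i += 1
        if self.x_equal:
            x = np.full(n, vec[i]); i += 1
        else:
            x = vec[i:i + n].copy(); i += n
        d = np.zeros((n, n))
        if self.d_mode == "equal":
            d[:] = vec[i]; i += 1
            np.fill_diagonal(d, 0.0)
        elif self.d_mode == "symmetric":
            for a, b in combinations(range(n), 2):
                d[a, b] = d[b, a] = vec[i]; i += 1
        else:
            for a in range(n):
                for b in range(n):
                    if a != b:
                        d[a, b] = vec[i]; i += 1
        if i != vec.size:
            raise ValueError(f"expected {self.k(n)} free parameters, got {vec.size}")
        return GeoSSEParams(n=n, s=s, sx=sx, x=x, d=d)

    def pack(self, params: GeoSSEParams) -> np.ndarray:
        n = params.n
        out: list[float] = []
        out += [params.s.mean()] if self.s_equal else list(params.s)
        if not self.sx_zero:
            out.append(params.sx)
        out += [params.x.mean()] if self.x_equal else list(params.x)
        if self.d_mode == "equal":
            off = params.d[~np.eye(n, dtype=bool)]
            out.append(off.mean())
        elif self.d_mode == "symmetric":
            out += [0.5 * (params.d[a, b] + params.d[b, a])
                    for a, b in combinations(range(n), 2)]
        else:
            out += [params.d[a, b] for a in range(n) for b in range(n) if a != b]
        return np.array(out)


@dataclass
class TipStates:
    """Tip label -> occupied-region tuple, plus the clade sampling fraction."""

    states: dict[str, tuple[int, ...]]
    n: int
    f: float = 1.0
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        for label, st in self.states.items():
            if not st or any(not (0 <= r < self.n) for r in st):
                raise ValueError(f"invalid state {st} for tip {label!r}")
            self.states[label] = tuple(sorted(set(st)))
        if not (0.0 < self.f <= 1.0):
            raise ValueError("sampling fraction f must be in (0, 1]")


def read_tip_states(path, column: str, region_names: list[str],
                    f: float = 1.0, species_column: str = "species") -> TipStates:
    """Read a tip-state table (CSV); multi-region states are ';'-joined names."""
    df = pd.read_csv(path)
    idx = {name: i for i, name in enumerate(region_names)}
    out = {}
    for _, row in df.iterrows():
        parts = [p.strip() for p in str(row[column]).split(";") if p.strip()]
        unknown = [p for p in parts if p not in idx]
        if unknown:
            raise ValueError(f"unknown region(s) {unknown} for "
                             f"{row[species_column]!r} in column {column!r}")
        out[str(row[species_column])] = tuple(sorted(idx[p] for p in parts))
    return TipStates(states=out, n=len(region_names), f=f,
                     region_names=list(region_names))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _bipartitions(S: tuple[int, ...]):
    """Unordered bipartitions of S into two non-empty complementary subsets."""
    rest = S[1:]
    for r in range(len(rest) + 1):
        for sub in combinations(rest, r):
            s1 = (S[0],) + sub
            s2 = tuple(sorted(set(S) - set(s1)))
            if s2:
                yield s1, s2


def build_rate_arrays(params: GeoSSEParams):
    """Assemble the anagenetic matrix, extinction constants and cladogenetic
    event list consumed by the compiled pruning kernel."""
    st = states(params.n)
    index = {S: i for i, S in enumerate(st)}
    m = len(st)
    M = np.zeros((m, m))
    extc = np.zeros(m)
    lam_tot = np.zeros(m)
    clp, cla, clb, clr = [], [], [], []
    for si, S in enumerate(st):
        sset = set(S)
        total = 0.0
        # anagenetic range expansion
        for j in range(params.n):
            if j not in sset:
                rate = sum(params.d[i, j] for i in S)
                if rate > 0.0:
                    M[si, index[tuple(sorted(S + (j,)))]] += rate
                total += rate
        # extirpation / extinction
        if len(S) > 1:
            for i in S:
                M[si, index[tuple(r for r in S if r != i)]] += params.x[i]
                total += params.x[i]
        else:
            extc[si] = params.x[S[0]]
            total += params.x[S[0]]
        # cladogenesis: within-region
        for i in S:
            if params.s[i] > 0.0 or True:
                clp.append(si)
                cla.append(index[(i,)])
                clb.append(si)
                clr.append(params.s[i])
            total += params.s[i]
            lam_tot[si] += params.s[i]
        # cladogenesis: state-change (vicariant)
        if len(S) > 1 and params.sx > 0.0:
            bips = list(_bipartitions(S))
            rate = params.sx / len(bips)
            for s1, s2 in bips:
                clp.append(si)
                cla.append(index[s1])
                clb.append(index[s2])
                clr.append(rate)
            total += params.sx
            lam_tot[si] += params.sx
        M[si, si] = -total
    return (M, extc,
            np.asarray(clp, dtype=np.int64), np.asarray(cla, dtype=np.int64),
            np.asarray(clb, dtype=np.int64), np.asarray(clr, dtype=float),
            lam_tot)


def _tip_state_vector(tree: Tree, tips: TipStates) -> tuple:
    post = tree.postorder_arrays()
    index = {S: i for i, S in enumerate(states(tips.n))}
    tip_state = np.full(post.age.shape[0], -1, dtype=np.int64)
    missing = []
    for node_i, ti in enumerate(post.tip_index):
        if ti >= 0:
            label = post.tip_labels[ti]
            if label not in tips.states:
                missing.append(label)
            else:
                tip_state[node_i] = index[tips.states[label]]
    if missing:
        raise ValueError(f"tips without state data: {sorted(missing)}")
    return post, tip_state


def classe_loglik(tree: Tree, tips: TipStates, params: GeoSSEParams,
                  conditioning: str = "none", h: float = _DEFAULT_H,
                  root: str = "obs",
                  _mask: tuple[int, int] | None = None) -> float:
    """Log-likelihood of tree + tip states under the n-region model.

    ``root="obs"`` weights root states proportionally to their likelihood
    (FitzJohn-style, the default); ``root="flat"`` weights them equally.
    ``conditioning="survival"`` additionally divides by the probability
    that both basal lineages leave sampled descendants. Both choices are
    shared constants across compared models.
    """
    if conditioning not in ("none", "survival"):
        raise ValueError("conditioning must be 'none' or 'survival'")
    if root not in ("obs", "flat"):
        raise ValueError("root must be 'obs' or 'flat'")
    post, tip_state = _tip_state_vector(tree, tips)
    M, extc, clp, cla, clb, clr, lam_tot = build_rate_arrays(params)
    mask_node, mask_state = _mask if _mask is not None else (-1, -1)
    ok, logscale, E_root, D_root = classe_prune(
        post.age, post.left, post.right, tip_state, post.parent_age,
        M, extc, clp, cla, clb, clr, tips.f, h, mask_node, mask_state)
    if not ok:
        return -np.inf
    # D_root is already normalized to sum 1
    w = D_root if root == "obs" else np.full_like(D_root, 1.0 / D_root.size)
    lnl = logscale + np.log(np.dot(w, D_root))
    if conditioning == "survival":
        denom = np.dot(w, lam_tot * (1.0 - E_root) ** 2)
        if denom <= 0.0:
            return -np.inf
        lnl -= np.log(denom)
    return float(lnl)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

@dataclass
class SSEFit:
    params: GeoSSEParams
    constraints: Constraints
    vec: np.ndarray
    param_names: list[str]
    lnl: float
    k: int
    aic: float
    converged: bool
    shared: bool
    clade_lnls: list[float] = field(default_factory=list)


def _joint_sse_loglik(clades, params, conditioning, h):
    total = 0.0
    parts = []
    for tree, tips in clades:
        lnl = classe_loglik(tree, tips, params, conditioning, h)
        if not np.isfinite(lnl):
            return -np.inf, []
        parts.append(lnl)
        total += lnl
    return total, parts


def _yule_rate(clades) -> float:
    rs = [np.log(max(t.n_tips, 3) / 2.0) / t.crown_age for t, _ in clades]
    return max(float(np.mean(rs)), 1e-3)


def fit_sse(clades, constraints: Constraints, *, shared: bool = True,
            n_starts: int = 3, seed: int | None = 0,
            conditioning: str = "none", h: float = _DEFAULT_H,
            start: GeoSSEParams | None = None):
    """ML fit of the constrained model by simplex in log-rate space.

    ``clades`` is a list of (Tree, TipStates) pairs (a single pair is also
    accepted). With ``shared=True`` one parameter vector is fitted jointly
    (likelihoods multiplied); with ``shared=False`` a list of per-clade
    fits is returned.
    """
    from scipy.optimize import minimize

    if isinstance(clades, tuple) and isinstance(clades[0], Tree):
        clades = [clades]
    if not shared:
        return [fit_sse([c], constraints, shared=True, n_starts=n_starts,
                        seed=seed, conditioning=conditioning, h=h, start=start)
                for c in clades]

    n = clades[0][1].n
    if any(tp.n != n for _, tp in clades):
        raise ValueError("all clades must share the region definitions")
    names = constraints.param_names(n)
    kk = len(names)

    if start is None:
        r0 = _yule_rate(clades)
        start_params = GeoSSEParams.uniform(n, s=r0, sx=0.5 * r0,
                                            x=0.25 * r0, d=0.5 * r0)
    else:
        start_params = start
    v0 = np.maximum(constraints.pack(start_params), 1e-6)

    def nobj(z):
        params = constraints.unpack(n, np.exp(z))
        lnl, _ = _joint_sse_loglik(clades, params, conditioning, h)
        return -lnl if np.isfinite(lnl) else 1e12

    rng = np.random.default_rng(seed)
    starts = [np.log(v0)]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(np.log(v0) + rng.normal(0.0, 0.4, size=kk))
    best = None
    any_ok = False
    for z0 in starts:
        res = minimize(nobj, z0, method="Nelder-Mead",
                       options={"maxiter": 400 * kk, "xatol": 1e-6,
                                "fatol": 1e-8})
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    vec = np.exp(best.x)
    params = constraints.unpack(n, vec)
    lnl, parts = _joint_sse_loglik(clades, params, conditioning, h)
    return SSEFit(params=params, constraints=constraints, vec=vec,
                  param_names=names, lnl=float(lnl), k=kk,
                  aic=float(-2.0 * lnl + 2.0 * kk), converged=any_ok,
                  shared=True, clade_lnls=[float(p) for p in parts])


def aicdiff_sse(null_fit: SSEFit, focal_fit: SSEFit) -> float:
    """AIC(null) - AIC(focal) for nested constraint sets."""
    if null_fit.k >= focal_fit.k:
        raise ValueError("null model must have fewer free parameters")
    return float(null_fit.aic - focal_fit.aic)


_TESTS = {
    # test name -> (feature freed in the focal model, constrained in the null)
    "state_change_speciation": ("sx", {"null": {"sx_zero": True},
                                       "focal": {"sx_zero": False}}),
    "speciation_rate_difference": ("s", {"null": {"s_equal": True},
                                         "focal": {"s_equal": False}}),
    "extinction_rate_difference": ("x", {"null": {"x_equal": True},
                                         "focal": {"x_equal": False}}),
    "migration_directionality": ("d", {"null": {"d_mode": "symmetric"},
                                       "focal": {"d_mode": "free"}}),
}


def aicdiff_tests(clades, *, base: Constraints | None = None,
                  shared: bool = True, n_starts: int = 3,
                  seed: int | None = 0, conditioning: str = "none",
                  h: float = _DEFAULT_H) -> pd.DataFrame:
    """The four model-feature tests, each an AICdiff of focal vs nested null.

    (i) presence of state-change speciation, (ii) per-region differences in
    constant-state speciation, (iii) per-region differences in extinction,
    (iv) directionality of migration. Each test frees/constrains one
    feature around the ``base`` constraint set and reports its df.
    """
    if isinstance(clades, tuple) and isinstance(clades[0], Tree):
        clades = [clades]
    base = base or Constraints()
    n = clades[0][1].n
    rows = []
    for test, (_feat, sides) in _TESTS.items():
        null_c = replace(base, **sides["null"])
        focal_c = replace(base, **sides["focal"])
        if null_c.k(n) >= focal_c.k(n):
            continue
        nf = fit_sse(clades, null_c, shared=shared, n_starts=n_starts,
                     seed=seed, conditioning=conditioning, h=h)
        ff = fit_sse(clades, focal_c, shared=shared, n_starts=n_starts,
                     seed=seed, conditioning=conditioning, h=h,
                     start=nf.params)
        rows.append({"test": test, "df": focal_c.k(n) - null_c.k(n),
                     "lnl_null": nf.lnl, "lnl_focal": ff.lnl,
                     "aic_null": nf.aic, "aic_focal": ff.aic,
                     "aicdiff": nf.aic - ff.aic})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bayesian rerun: univariate slice sampling
# ---------------------------------------------------------------------------

@dataclass
class SSEChain:
    samples: pd.DataFrame        # post-burn-in draws, one column per parameter
    n_iterations: int
    burnin: int
    prior_means: np.ndarray
    mean_evals_per_update: float

    def credible_interval(self, level: float = 0.95) -> pd.DataFrame:
        a = (1.0 - level) / 2.0
        qs = self.samples.quantile([a, 0.5, 1.0 - a]).T
        qs.columns = ["lower", "median", "upper"]
        qs["mean"] = self.samples.mean()
        return qs


def slice_sample(logdensity, x0: np.ndarray, n_iter: int,
                 seed: int | None = 0, widths: np.ndarray | None = None,
                 lower: float = 0.0, max_steps: int = 100):
    """Univariate slice sampler (stepping out + shrinkage), cycling over
    coordinates; coordinates are bounded below by ``lower``."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    k = x.size
    widths = (np.maximum(np.abs(x), 0.1) if widths is None
              else np.asarray(widths, dtype=float))
    out = np.empty((n_iter, k))
    lp = logdensity(x)
    if not np.isfinite(lp):
        raise ValueError("slice sampler must start at a finite-density point")
    n_evals = 0
    for it in range(n_iter):
        for j in range(k):
            logy = lp + np.log(rng.uniform())
            w = widths[j]
            L = x[j] - w * rng.uniform()
            R = L + w
            L = max(L, lower)
            steps = 0
            xj = x[j]

            def at(v):
                nonlocal n_evals
                n_evals += 1
                x[j] = v
                return logdensity(x)

            while L > lower and at(L) > logy and steps < max_steps:
                L = max(L - w, lower)
                steps += 1
            while at(R) > logy and steps < max_steps:
                R += w
                steps += 1
            # shrinkage
            while True:
                if R - L < 1e-300:
                    raise RuntimeError("slice collapsed to zero width "
                                       "(pathological posterior)")
                v = rng.uniform(L, R)
                lp_v = at(v)
                if lp_v > logy:
                    x[j] = v
                    lp = lp_v
                    break
                if v < xj:
                    L = v
                else:
                    R = v
        out[it] = x
    return out, n_evals / (n_iter * k)


def mcmc_slice(clades, fit: SSEFit, *, iterations: int = 10_000,
               burnin: int = 5_000, prior_means: np.ndarray | None = None,
               seed: int | None = 0, conditioning: str = "none",
               h: float = _DEFAULT_H) -> SSEChain:
    """Bayesian rerun of a fitted model with a slice-sampling MCMC.

    Priors are independent exponentials on each free rate; by default the
    prior mean is twice the clade set's overall Yule-rate estimate -- a
    weakly informative, scale-aware choice that is recorded in the chain.
    The chain starts at the ML fit.
    """
    if isinstance(clades, tuple) and isinstance(clades[0], Tree):
        clades = [clades]
    n = clades[0][1].n
    cons = fit.constraints
    if prior_means is None:
        prior_means = np.full(fit.k, 2.0 * _yule_rate(clades))
    prior_means = np.asarray(prior_means, dtype=float)

    def logpost(vec):
        if (vec < 0.0).any():
            return -np.inf
        params = cons.unpack(n, vec)
        lnl, _ = _joint_sse_loglik(clades, params, conditioning, h)
        if not np.isfinite(lnl):
            return -np.inf
        return lnl - np.sum(vec / prior_means) - np.sum(np.log(prior_means))

    x0 = np.maximum(fit.vec, 1e-8)
    draws, mean_evals = slice_sample(logpost, x0, iterations, seed=seed,
                                     widths=np.maximum(x0, 0.05))
    samples = pd.DataFrame(draws[burnin:], columns=fit.param_names)
    return SSEChain(samples=samples, n_iterations=iterations, burnin=burnin,
                    prior_means=prior_means, mean_evals_per_update=mean_evals)


# ---------------------------------------------------------------------------
# marginal ancestral states
# ---------------------------------------------------------------------------

def asr_marginal(tree: Tree, tips: TipStates, params: GeoSSEParams,
                 h: float = _DEFAULT_H) -> pd.DataFrame:
    """Marginal state probabilities for every internal node.

    For each node and state the tree likelihood is recomputed with that
    node's state restricted, holding the root weighting fixed at the
    unrestricted run's likelihood-proportional weights; probabilities are
    the normalized restricted likelihoods. Rows sum to 1.
    """
    post, tip_state = _tip_state_vector(tree, tips)
    M, extc, clp, cla, clb, clr, _ = build_rate_arrays(params)
    ok, _, _, D_root = classe_prune(
        post.age, post.left, post.right, tip_state, post.parent_age,
        M, extc, clp, cla, clb, clr, tips.f, h, -1, -1)
    if not ok:
        raise RuntimeError("likelihood underflow in ancestral reconstruction")
    w = D_root
    st = states(tips.n)
    m = len(st)
    rows = []
    internal = np.where(post.left >= 0)[0]
    for node in internal:
        lls = np.full(m, -np.inf)
        for s in range(m):
            ok, logscale, _, D_m = classe_prune(
                post.age, post.left, post.right, tip_state, post.parent_age,
                M, extc, clp, cla, clb, clr, tips.f, h, int(node), s)
            if ok:
                tot = float(np.dot(w, D_m))
                if tot > 0.0:
                    lls[s] = logscale + np.log(tot)
        pr = np.exp(lls - lls.max())
        pr /= pr.sum()
        rows.append({"node": int(node), "age": float(post.age[node]),
                     **{"p_" + "".join(str(r) for r in S): pr[i]
                        for i, S in enumerate(st)}})
    return pd.DataFrame(rows)


def state_change_proportion(tip_counts, params: GeoSSEParams) -> float:
    """Share of speciation events that are state-change (vicariant).

    Present-day species counts per state are multiplied by their state's
    speciation rates: widespread states speciate at sum_i s_i + s_x, and
    the s_x share of that total is the state-change fraction.
    """
    st = states(params.n)
    if isinstance(tip_counts, dict):
        counts = np.array([float(tip_counts.get(S, 0.0)) for S in st])
    else:
        counts = np.asarray(tip_counts, dtype=float)
        if counts.shape != (len(st),):
            raise ValueError(f"need one count per state ({len(st)})")
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    num = 0.0
    den = 0.0
    for i, S in enumerate(st):
        within = sum(params.s[r] for r in S)
        change = params.sx if len(S) > 1 else 0.0
        num += counts[i] * change
        den += counts[i] * (within + change)
    if den <= 0.0:
        raise ZeroDivisionError("total speciation flux is zero")
    return float(num / den)


def tip_state_counts(tips: TipStates) -> dict[tuple[int, ...], int]:
    """Present-day species counts per model state."""
    counts: dict[tuple[int, ...], int] = {}
    for st_tuple in tips.states.values():
        counts[st_tuple] = counts.get(st_tuple, 0) + 1
    return counts
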