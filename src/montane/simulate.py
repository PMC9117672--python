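"""Synthetic data with the statistical structure the analyses assume.

Forward birth-death trees with time-varying rates (thinning algorithm),
Gillespie simulation of the n-region cladogenetic model, a synthetic
paleotemperature proxy (gradual cooling plus late oscillations), synthetic
occupancy tables with a planted allopatric fraction, and the sensitivity
experiment that measures the power to detect a Pleistocene drop of the
speciation rate.

The default six-clade template mirrors the study system: clade sizes
(known species counts 29, 50, 35, 27, 24, 86), sampling fractions from the
sampled/known counts, and crown ages drawn within each clade's credibility
window. All randomness flows from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bd import BDModelSpec, CladeData
from .geosse import GeoSSEParams, TipStates, build_rate_arrays, states
from .multiclade import CladeSet, fit_shared, _focal_start
from .overlap import OccupancyTable
from .paleo import PaleoCurve
from .trees import Tree

__all__ = [
    "CladeTemplate", "DEFAULT_TEMPLATE",
    "sim_bd_tree", "sim_geosse_tree", "sim_paleocurve", "sim_occupancy",
    "pleistocene_step_curve", "simulate_template_cladeset",
    "sensitivity_power",
]


@dataclass(frozen=True)
class CladeTemplate:
    name: str
    n_known: int
    n_sampled: int
    crown_window: tuple[float, float]   # Ma BP

    @property
    def f(self) -> float:
        return self.n_sampled / self.n_known


DEFAULT_TEMPLATE = (
    CladeTemplate("Androsace", 29, 26, (4.7, 10.7)),
    CladeTemplate("Campanula", 50, 45, (10.1, 16.5)),
    CladeTemplate("Gentiana", 35, 28, (6.4, 28.5)),
    CladeTemplate("Phyteuma", 27, 27, (13.7, 24.5)),
    CladeTemplate("Primula", 24, 24, (3.2, 7.9)),
    CladeTemplate("Saxifraga", 86, 62, (12.5, 38.1)),
)


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# lineage bookkeeping and reduction to a sampled, ultrametric tree
# ---------------------------------------------------------------------------

class _Lin:
    __slots__ = ("parent", "t0", "t1", "children", "state", "alive")

    def __init__(self, parent, t0, state=None):
        self.parent = parent
        self.t0 = t0          # forward birth time
        self.t1 = None        # forward end time (speciation/extinction/present)
        self.children = []
        self.state = state
        self.alive = True


def _reduce_to_newick(roots, kept, present):
    """Reduce the full event tree to the sampled survivors, as Newick.

    ``kept`` maps lineage -> tip label for the sampled extant lineages.
    Returns None if fewer than two tips remain.
    """
    # kept-descendant counts, iterative postorder
    order = []
    stack = list(roots)
    while stack:
        lin = stack.pop()
        order.append(lin)
        stack.extend(lin.children)
    ndesc = {}
    for lin in reversed(order):
        ndesc[id(lin)] = ((1 if lin in kept else 0)
                          + sum(ndesc[id(c)] for c in lin.children))

    def reduce(lin):
        # -> (time, newick-subtree-without-length) or None
        if lin in kept:
            return present, kept[lin]
        kids = [reduce(c) for c in lin.children if ndesc[id(c)] > 0]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        (ta, sa), (tb, sb) = kids
        t = lin.t1
        return t, f"({sa}:{ta - t:.10f},{sb}:{tb - t:.10f})"

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(order) + 100))
    try:
        tops = [reduce(r) for r in roots]
    finally:
        sys.setrecursionlimit(old)
    tops = [t for t in tops if t is not None]
    if not tops:
        return None
    if len(tops) == 1:
        t, s = tops[0]
        if "(" not in s:
            return None  # a single surviving tip is not a tree
        return s + ";"
    (ta, sa), (tb, sb) = tops
    return f"({sa}:{ta:.10f},{sb}:{tb:.10f});"


def _as_rate_fn(rate):
    if callable(rate):
        return rate
    return lambda t, r=float(rate): r


# ---------------------------------------------------------------------------
# birth-death simulation (thinning)
# ---------------------------------------------------------------------------

def sim_bd_tree(*, lam, mu=0.0, crown_age=None, n_tips=None, f=1.0,
                seed, tip_cap=20_000, max_attempts=1_000,
                require_crown_survival=False, label_prefix="t") -> Tree:
    """Forward birth-death tree from two crown lineages.

    ``lam`` and ``mu`` are either constants or callables of age (Ma BP);
    time-varying rates are simulated exactly by thinning at their upper
    bound over the simulated interval. Exactly one stopping rule applies:
    ``crown_age`` (simulate to the present) or ``n_tips`` (stop shortly
    after the extant count first reaches the target; constant rates only).
    Extinct lineages are pruned, survivors are subsampled binomially at
    ``f``, and the whole simulation is conditioned on >= 2 sampled
    survivors by resimulation. ``require_crown_survival=True`` additionally
    conditions on both crown lineages leaving sampled descendants (so the
    sampled tree's crown age equals ``crown_age``), matching the crown
    conditioning of the likelihood; use it for recovery experiments fitted
    with crown conditioning.
    """
    if (crown_age is None) == (n_tips is None):
        raise ValueError("give exactly one of crown_age or n_tips")
    if n_tips is not None and (callable(lam) or callable(mu)):
        raise ValueError("n_tips stopping requires constant rates")
    rng = np.random.default_rng(seed)
    lam_f, mu_f = _as_rate_fn(lam), _as_rate_fn(mu)

    if crown_age is not None:
        grid = np.linspace(0.0, crown_age, 2049)
        bound = float(max(lam_f(t) + mu_f(t) for t in grid))
    else:
        bound = float(lam_f(0.0) + mu_f(0.0))
    if not np.isfinite(bound) or bound <= 0.0:
        raise ValueError("per-lineage event-rate bound must be positive and finite")

    for _attempt in range(max_attempts):
        roots = [_Lin(None, 0.0), _Lin(None, 0.0)]
        active = list(roots)
        tau = 0.0
        horizon = crown_age if crown_age is not None else np.inf
        failed = False
        while active:
            total = len(active) * bound
            tau_next = tau + rng.exponential(1.0 / total)
            if n_tips is not None and len(active) >= n_tips:
                # stop at a uniform point before the next event
                horizon = tau + rng.uniform() * (tau_next - tau)
                break
            if tau_next >= horizon:
                break
            tau = tau_next
            age = horizon - tau if crown_age is not None else 0.0
            if crown_age is not None:
                age = crown_age - tau
            lin = active[rng.integers(len(active))]
            u = rng.uniform(0.0, bound)
            lam_t = lam_f(age)
            if u < lam_t:
                lin.t1 = tau
                lin.alive = False
                lin.children = [_Lin(lin, tau), _Lin(lin, tau)]
                active.remove(lin)
                active.extend(lin.children)
            elif u < lam_t + mu_f(age):
                lin.t1 = tau
                lin.alive = False
                active.remove(lin)
            if len(active) > tip_cap:
                raise SimulationError(f"tip cap {tip_cap} exceeded")
        if not active:
            continue
        present = horizon if np.isfinite(horizon) else tau
        for lin in active:
            lin.t1 = present
        sampled = [lin for lin in active if rng.uniform() < f]
        if len(sampled) < 2:
            failed = True
        if failed:
            continue
        if require_crown_survival and crown_age is not None:
            sampled_set = set(sampled)
            if not all(any(lin in sampled_set for lin in _descendants(root))
                       for root in roots):
                continue
        kept = {lin: f"{label_prefix}{i}" for i, lin in enumerate(sampled)}
        newick = _reduce_to_newick(roots, kept, present)
        if newick is None:
            continue
        return Tree.from_newick(newick)
    raise SimulationError(f"no surviving tree in {max_attempts} attempts")


def _descendants(lin):
    stack = [lin]
    while stack:
        cur = stack.pop()
        yield cur
        stack.extend(cur.children)


# ---------------------------------------------------------------------------
# Gillespie simulation of the n-region cladogenetic model
# ---------------------------------------------------------------------------

def _event_table(params: GeoSSEParams):
    """Per-state event menus for the Gillespie simulator.

    Events are drawn from exactly the rates that define the likelihood:
    the anagenetic matrix rows plus extinction, and the cladogenetic list
    with its bipartition convention.
    """
    st = states(params.n)
    M, extc, clp, cla, clb, clr, _ = build_rate_arrays(params)
    menus = []
    for si, S in enumerate(st):
        events = []   # (rate, kind, payload)
        for sj in range(len(st)):
            if sj != si and M[si, sj] > 0.0:
                events.append((M[si, sj], "move", sj))
        if extc[si] > 0.0:
            events.append((extc[si], "die", None))
        for k in range(clp.shape[0]):
            if clp[k] == si and clr[k] > 0.0:
                events.append((clr[k], "split", (int(cla[k]), int(clb[k]))))
        rates = np.array([e[0] for e in events])
        menus.append((rates.sum(), np.cumsum(rates), events))
    return st, menus


def sim_geosse_tree(params: GeoSSEParams, *, root_state, crown_age=None,
                    n_tips=None, f=1.0, seed, tip_cap=20_000,
                    max_attempts=1_000,
                    label_prefix="t") -> tuple[Tree, TipStates]:
    """Gillespie simulation of the n-region model from two crown lineages.

    ``root_state`` is the occupied-region tuple of both crown lineages.
    Events (range expansion, extirpation/extinction, within-region and
    state-change speciation) are drawn from exactly the rates of the
    likelihood model. Returns the sampled tree and its tip states.
    """
    if (crown_age is None) == (n_tips is None):
        raise ValueError("give exactly one of crown_age or n_tips")
    rng = np.random.default_rng(seed)
    st, menus = _event_table(params)
    index = {S: i for i, S in enumerate(st)}
    s0 = index[tuple(sorted(root_state))]

    for _attempt in range(max_attempts):
        roots = [_Lin(None, 0.0, s0), _Lin(None, 0.0, s0)]
        active = list(roots)
        tau = 0.0
        horizon = crown_age if crown_age is not None else np.inf
        while active:
            rates = np.array([menus[lin.state][0] for lin in active])
            total = rates.sum()
            if total <= 0.0:
                break  # absorbing configuration; run to the horizon
            tau_next = tau + rng.exponential(1.0 / total)
            if n_tips is not None and len(active) >= n_tips:
                horizon = tau + rng.uniform() * (tau_next - tau)
                break
            if tau_next >= horizon:
                break
            tau = tau_next
            lin = active[rng.choice(len(active), p=rates / total)]
            _, cum, events = menus[lin.state]
            ev = events[int(np.searchsorted(cum, rng.uniform(0.0, cum[-1])))]
            _, kind, payload = ev
            if kind == "move":
                lin.state = payload
            elif kind == "die":
                lin.t1 = tau
                lin.alive = False
                active.remove(lin)
            else:  # split
                a, b = payload
                lin.t1 = tau
                lin.alive = False
                lin.children = [_Lin(lin, tau, a), _Lin(lin, tau, b)]
                active.remove(lin)
                active.extend(lin.children)
            if len(active) > tip_cap:
                raise SimulationError(f"tip cap {tip_cap} exceeded")
        if not active:
            continue
        present = horizon if np.isfinite(horizon) else tau
        if n_tips is not None and np.isinf(present):
            present = tau
        for lin in active:
            lin.t1 = present
        sampled = [lin for lin in active if rng.uniform() < f]
        if len(sampled) < 2:
            continue
        kept = {lin: f"{label_prefix}{i}" for i, lin in enumerate(sampled)}
        newick = _reduce_to_newick(roots, kept, present)
        if newick is None:
            continue
        tree = Tree.from_newick(newick)
        tip_states = {kept[lin]: st[lin.state] for lin in sampled}
        return tree, TipStates(states=tip_states, n=params.n, f=f)
    raise SimulationError(f"no surviving tree in {max_attempts} attempts")


# ---------------------------------------------------------------------------
# synthetic paleotemperature proxy
# ---------------------------------------------------------------------------

def sim_paleocurve(*, seed, max_age=40.0, cooling=8.0, osc_amplitude=1.0,
                   osc_period=0.1, noise_sd=0.1,
                   pleistocene_onset=2.6) -> PaleoCurve:
    """A cooling-trend proxy with oscillations confined to the Pleistocene.

    Values are on a "warmer is larger" orientation: the linear trend adds
    ``cooling`` proxy units at ``max_age`` relative to the present, and a
    seeded sinusoid-plus-noise of amplitude ``osc_amplitude`` is applied
    for ages younger than ``pleistocene_onset``. Amplitude 0 gives a
    strictly monotone curve.
    """
    rng = np.random.default_rng(seed)
    fine = np.arange(0.0, pleistocene_onset, 0.02)
    coarse = np.arange(pleistocene_onset, max_age + 1e-9, 0.5)
    ages = np.concatenate([fine, coarse])
    values = cooling * ages / max_age
    young = ages < pleistocene_onset
    values[young] += osc_amplitude * (
        np.sin(2.0 * np.pi * ages[young] / osc_period)
        + noise_sd * rng.standard_normal(young.sum()))
    return PaleoCurve(ages=ages, values=values, orientation="warmer")


def pleistocene_step_curve(onset: float = 2.6, max_age: float = 45.0,
                           ramp: float = 1e-6) -> PaleoCurve:
    """A 0/1 proxy that is 1 before ``onset`` (warm) and 0 after it."""
    return PaleoCurve(ages=np.array([0.0, onset, onset + ramp, max_age]),
                      values=np.array([0.0, 0.0, 1.0, 1.0]),
                      orientation="warmer")


# ---------------------------------------------------------------------------
# synthetic occupancy tables
# ---------------------------------------------------------------------------

def sim_occupancy(tree: Tree, *, allopatric_fraction=0.0, n_units=87,
                  n_regions=5, range_size=6, both_prob=0.3, seed) -> OccupancyTable:
    """Occupancy over fine units with a planted allopatric cherry fraction.

    Exactly ``allopatric_fraction`` of the tree's cherries are made fully
    disjoint at the fine geographic scale; all other cherries share at
    least one unit. The fraction must be representable as a whole number
    of cherries, else the request is infeasible and raises. Bedrock and
    elevation states are drawn independently per species.
    """
    rng = np.random.default_rng(seed)
    pairs = tree.cherries()
    n_pairs = len(pairs)
    n_allo_f = allopatric_fraction * n_pairs
    n_allo = round(n_allo_f)
    if abs(n_allo - n_allo_f) > 1e-9:
        raise ValueError(
            f"allopatric fraction {allopatric_fraction} infeasible for "
            f"{n_pairs} cherries")
    if 2 * range_size > n_units:
        raise ValueError("range_size too large for disjoint pairs")
    units = [f"u{i:02d}" for i in range(n_units)]
    sizes = np.full(n_regions, n_units // n_regions)
    sizes[: n_units % n_regions] += 1
    unit_to_region = {}
    pos = 0
    for r, size in enumerate(sizes):
        for u in units[pos:pos + size]:
            unit_to_region[u] = f"R{r + 1}"
        pos += size

    occ = pd.DataFrame(0, index=tree.tip_labels, columns=units)
    chosen = rng.permutation(n_pairs)[:n_allo]
    allo = set(chosen.tolist())
    in_pair = set()
    for ip, pair in enumerate(pairs):
        in_pair |= {pair.a, pair.b}
        if ip in allo:
            pick = rng.choice(n_units, size=2 * range_size, replace=False)
            occ.loc[pair.a, [units[i] for i in pick[:range_size]]] = 1
            occ.loc[pair.b, [units[i] for i in pick[range_size:]]] = 1
        else:
            shared = int(rng.integers(n_units))
            for sp in (pair.a, pair.b):
                pick = rng.choice(n_units, size=range_size, replace=False)
                occ.loc[sp, [units[i] for i in pick]] = 1
                occ.loc[sp, units[shared]] = 1
    for sp in tree.tip_labels:
        if sp not in in_pair:
            pick = rng.choice(n_units, size=range_size, replace=False)
            occ.loc[sp, [units[i] for i in pick]] = 1

    def _two_state(prob_both):
        rows = []
        for _sp in tree.tip_labels:
            u = rng.uniform()
            if u < prob_both:
                rows.append((1, 1))
            elif u < prob_both + (1.0 - prob_both) / 2.0:
                rows.append((1, 0))
            else:
                rows.append((0, 1))
        return rows

    bedrock = pd.DataFrame(_two_state(both_prob), index=tree.tip_labels,
                           columns=["calcareous", "siliceous"])
    elevation = pd.DataFrame(_two_state(both_prob), index=tree.tip_labels,
                             columns=["high", "mid"])
    return OccupancyTable(units=occ, unit_to_region=unit_to_region,
                          bedrock=bedrock, elevation=elevation)


def simulate_constant_rate_cladeset(*, lam, mu, seed,
                                    template=DEFAULT_TEMPLATE) -> CladeSet:
    """Six constant-rate clades sized like the dataset, for recovery tests.

    Crown ages are set so the expected sampled richness matches each
    template clade (T = ln(N_known/2) / (lam - mu)); simulations are
    conditioned on both crown lineages leaving sampled descendants, the
    same crown conditioning the likelihood uses.
    """
    rng = np.random.default_rng(seed)
    clades = []
    for tpl in template:
        T = np.log(tpl.n_known / 2.0) / (lam - mu)
        tree = sim_bd_tree(lam=lam, mu=mu, crown_age=T, f=tpl.f,
                           seed=int(rng.integers(2 ** 31)),
                           require_crown_survival=True,
                           label_prefix=f"{tpl.name[:3]}_")
        clades.append(CladeData(tree=tree, f=tpl.f, name=tpl.name))
    return CladeSet(clades)


# ---------------------------------------------------------------------------
# sensitivity / power experiment
# ---------------------------------------------------------------------------

def simulate_template_cladeset(*, drop_factor=1.0, seed,
                               template=DEFAULT_TEMPLATE,
                               mu_fraction=0.2, onset=2.6,
                               curve: PaleoCurve | None = None) -> CladeSet:
    """Six clades whose speciation rate drops to ``drop_factor`` of its
    Tertiary value at the Pleistocene onset, acting through the 0/1 step
    covariate (so the fitted temperature model sees exactly this signal).
    """
    curve = curve or pleistocene_step_curve(onset)
    rng = np.random.default_rng(seed)
    clades = []
    for tpl in template:
        T = rng.uniform(*tpl.crown_window)
        r = np.log(tpl.n_known / 2.0) / T
        lam_tert = r / (1.0 - mu_fraction)
        mu = mu_fraction * lam_tert
        lam0 = drop_factor * lam_tert               # rate at covariate 0
        alpha = np.log(1.0 / drop_factor) if drop_factor < 1.0 else 0.0
        lam_fn = (lambda t, l0=lam0, a=alpha, c=curve:
                  l0 * np.exp(a * c.at(min(t, c.max_age))))
        tree = sim_bd_tree(lam=lam_fn, mu=mu, crown_age=T, f=tpl.f,
                           seed=int(rng.integers(2 ** 31)),
                           label_prefix=f"{tpl.name[:3]}_")
        clades.append(CladeData(tree=tree, f=tpl.f, curve=curve, name=tpl.name))
    return CladeSet(clades)


def sensitivity_power(drop_factors, nsim: int, *, seed,
                      template=DEFAULT_TEMPLATE, aic_threshold=2.0,
                      n_starts=2, h=0.02) -> pd.DataFrame:
    """Power to detect a Pleistocene speciation drop with the shared
    temperature-dependent model.

    For each drop factor, ``nsim`` six-clade datasets are simulated with
    the speciation rate dropping to that fraction at 2.6 Ma BP; the shared
    constant-rate null and the shared temperature-dependent model are
    fitted and the fraction of replicates with AICdiff > ``aic_threshold``
    is the power. The drop factor 1.0 row measures the false-positive
    rate. Fit failures are counted, not fatal.
    """
    drop_factors = list(drop_factors)
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    if any(not (0.0 < d <= 1.0) for d in drop_factors):
        raise ValueError("drop factors must be in (0, 1]")
    rng = np.random.default_rng(seed)
    null_spec = BDModelSpec("BCST_DCST")
    focal_spec = BDModelSpec("BTEMP_DCST")
    curve = pleistocene_step_curve()
    rows = []
    for drop in drop_factors:
        hits = 0
        n_ok = 0
        n_failed = 0
        for _ in range(nsim):
            s = int(rng.integers(2 ** 31))
            try:
                cs = simulate_template_cladeset(drop_factor=drop, seed=s,
                                                template=template, curve=curve)
                nf = fit_shared(cs, null_spec, n_starts=n_starts, seed=s, h=h)
                ff = fit_shared(cs, focal_spec, n_starts=n_starts, seed=s, h=h,
                                extra_starts=[_focal_start(null_spec,
                                                           focal_spec,
                                                           nf.params)])
                n_ok += 1
                if nf.aic - ff.aic > aic_threshold:
                    hits += 1
            except (SimulationError, RuntimeError):
                n_failed += 1
        rows.append({"drop_factor": drop, "nsim": nsim, "n_ok": n_ok,
                     "n_failed": n_failed,
                     "power": hits / n_ok if n_ok else np.nan})
    return pd.DataFrame(rows)
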