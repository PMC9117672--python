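"""Joint (multi-clade) fitting of diversification models.

Each clade is treated as an independent realization of shared
diversification dynamics, so the joint likelihood is the product of the
per-clade likelihoods evaluated at one shared parameter vector. Sampling
fractions remain clade-specific (they are data properties, not model
parameters). Comparing the shared fit with the sum of lineage-specific
fits asks whether the dynamics really are shared: the lineage-specific
combination is the same joint model with every parameter clade-specific,
so the shared model is nested in it with k*(m-1) fewer degrees of freedom
for m clades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bd import (BDFit, BDModelSpec, CladeData, _DEFAULT_H, _params_vector,
                 bd_loglik, fit_bd, maximize_loglik, moment_start)
from .paleo import PaleoCurve
from .trees import Tree

__all__ = ["CladeSet", "SharedFit", "PosteriorBatch", "joint_loglik",
           "fit_shared", "compare_shared_vs_specific", "posterior_batch"]


@dataclass
class CladeSet:
    clades: list[CladeData]

    def __post_init__(self) -> None:
        if len(self.clades) < 2:
            raise ValueError("a CladeSet needs at least two clades")
        names = [c.name for c in self.clades]
        if len(set(names)) != len(names):
            raise ValueError(f"clade names must be unique, got {names}")

    def with_curve(self, curve: PaleoCurve) -> "CladeSet":
        return CladeSet([CladeData(tree=c.tree, f=c.f, curve=curve, name=c.name)
                         for c in self.clades])

    def __len__(self) -> int:
        return len(self.clades)


@dataclass
class SharedFit:
    spec: BDModelSpec
    params: dict[str, float]
    lnl: float
    clade_lnls: dict[str, float]
    aic: float
    converged: bool
    conditioning: str
    seed: int | None


@dataclass
class PosteriorBatch:
    table: pd.DataFrame           # one row per posterior draw
    median_aicdiff: float
    n_draws: int
    n_failed: int
    null_id: str
    focal_id: str


def joint_loglik(cladeset: CladeSet, spec: BDModelSpec, params,
                 conditioning: str = "crown", h: float = _DEFAULT_H) -> float:
    """Sum of per-clade log-likelihoods at one shared parameter vector."""
    total = 0.0
    for clade in cladeset.clades:
        try:
            lnl = bd_loglik(clade, spec, params, conditioning, h)
        except Exception as exc:
            raise RuntimeError(f"likelihood failed for clade "
                               f"{clade.name!r}: {exc}") from exc
        if not np.isfinite(lnl):
            return -np.inf
        total += lnl
    return total


def fit_shared(cladeset: CladeSet, spec: BDModelSpec, *, n_starts: int = 5,
               seed: int | None = 0, conditioning: str = "crown",
               h: float = _DEFAULT_H,
               extra_starts: list[dict] | None = None) -> SharedFit:
    """ML fit of one model with parameters shared across all clades."""
    # moments start pooled over clades
    starts = np.array([moment_start(spec, c.tree.n_tips, c.tree.crown_age)
                       for c in cladeset.clades])
    start = starts.mean(axis=0)
    extras = [_params_vector(spec, e) for e in (extra_starts or [])]
    vec, lnl, ok, _ = maximize_loglik(
        spec, lambda v: joint_loglik(cladeset, spec, v, conditioning, h),
        start, n_starts=n_starts, seed=seed, extra_starts=extras)
    clade_lnls = {c.name: bd_loglik(c, spec, vec, conditioning, h)
                  for c in cladeset.clades}
    assert abs(sum(clade_lnls.values()) - lnl) < 1e-9 * max(1.0, abs(lnl)) + 1e-9
    params = dict(zip(spec.param_names, (float(v) for v in vec)))
    return SharedFit(spec=spec, params=params, lnl=float(lnl),
                     clade_lnls={k: float(v) for k, v in clade_lnls.items()},
                     aic=float(-2.0 * lnl + 2.0 * spec.k), converged=ok,
                     conditioning=conditioning, seed=seed)


def compare_shared_vs_specific(cladeset: CladeSet, spec: BDModelSpec, *,
                               n_starts: int = 5, seed: int | None = 0,
                               conditioning: str = "crown",
                               h: float = _DEFAULT_H) -> dict:
    """AIC(shared) - sum of lineage-specific AICs; positive favors specific.

    The shared solution is supplied as an extra start to every
    lineage-specific fit, so the specific combination can never have a
    lower total likelihood; a violation indicates optimizer failure and
    raises.
    """
    shared = fit_shared(cladeset, spec, n_starts=n_starts, seed=seed,
                        conditioning=conditioning, h=h)
    specific: dict[str, BDFit] = {}
    for clade in cladeset.clades:
        fit = fit_bd(clade, spec, n_starts=n_starts, seed=seed,
                     conditioning=conditioning, h=h,
                     extra_starts=[shared.params])
        if not fit.converged:
            raise RuntimeError(f"lineage-specific fit failed for {clade.name!r}")
        specific[clade.name] = fit
    lnl_specific = sum(f.lnl for f in specific.values())
    if lnl_specific < shared.lnl - 1e-6:
        raise RuntimeError(
            "specific fits reached a lower joint likelihood than the shared "
            "fit; the optimizer failed to converge")
    m = len(cladeset)
    aic_specific = sum(f.aic for f in specific.values())
    return {
        "model_id": spec.model_id,
        "aic_shared": shared.aic,
        "aic_specific_sum": aic_specific,
        "aicdiff": shared.aic - aic_specific,
        "df": spec.k * (m - 1),
        "shared_fit": shared,
        "specific_fits": specific,
    }


def posterior_batch(tree_draws: list[list[Tree]], fs: list[float],
                    null_spec: BDModelSpec, focal_spec: BDModelSpec, *,
                    curve: PaleoCurve | None = None, names: list[str] | None = None,
                    n_starts: int = 3, seed: int | None = 0,
                    conditioning: str = "crown", h: float = _DEFAULT_H,
                    max_failed_fraction: float = 0.2) -> PosteriorBatch:
    """Fit a null/focal model pair on each posterior tree draw.

    ``tree_draws[i]`` holds one tree per clade for draw i (trees are paired
    across clades by draw index). Reports the per-draw AICdiff table and its
    median; aborts if more than ``max_failed_fraction`` of draws fail.
    """
    if not null_spec.nested_in(focal_spec):
        raise ValueError("null model must be nested in the focal model")
    names = names or [f"clade{i + 1}" for i in range(len(fs))]
    rows = []
    n_failed = 0
    for i, trees in enumerate(tree_draws):
        if len(trees) != len(fs):
            raise ValueError(f"draw {i} supplies {len(trees)} trees "
                             f"for {len(fs)} clades")
        cs = CladeSet([CladeData(tree=t, f=f, curve=curve, name=nm)
                       for t, f, nm in zip(trees, fs, names)])
        try:
            nf = fit_shared(cs, null_spec, n_starts=n_starts, seed=seed,
                            conditioning=conditioning, h=h)
            ff = fit_shared(cs, focal_spec, n_starts=n_starts, seed=seed,
                            conditioning=conditioning, h=h,
                            extra_starts=[_focal_start(null_spec, focal_spec,
                                                       nf.params)])
            rows.append({"draw": i, "lnl_null": nf.lnl, "lnl_focal": ff.lnl,
                         "aic_null": nf.aic, "aic_focal": ff.aic,
                         "aicdiff": nf.aic - ff.aic})
        except RuntimeError:
            n_failed += 1
    n = len(tree_draws)
    if n_failed > max_failed_fraction * n:
        raise RuntimeError(f"{n_failed}/{n} posterior draws failed to fit")
    table = pd.DataFrame(rows)
    return PosteriorBatch(table=table,
                          median_aicdiff=float(table["aicdiff"].median()),
                          n_draws=n, n_failed=n_failed,
                          null_id=null_spec.model_id,
                          focal_id=focal_spec.model_id)


def _focal_start(null_spec: BDModelSpec, focal_spec: BDModelSpec,
                 null_params: dict) -> dict:
    """Embed a null fit into the focal model (sensitivities at zero)."""
    start = {p: 0.0 for p in focal_spec.param_names}
    start.update({k: v for k, v in null_params.items() if k in start})
    return start
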