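"""Paleotemperature proxy curves.

A :class:`PaleoCurve` maps age (Ma BP) to a temperature proxy value and drives
the temperature-dependent rate functions of the diversification models. The
proxy orientation (whether larger values mean warmer or colder) is declared by
the caller, never guessed: temperature sensitivities are interpreted relative
to that declaration. Evaluation beyond the oldest tabulated age continues the
last value and emits a warning once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = ["PaleoCurve", "load_curve"]


@dataclass
class PaleoCurve:
    ages: np.ndarray          # Ma BP, strictly increasing, >= 0
    values: np.ndarray        # proxy units
    interpolation: str = "linear"   # "linear" | "spline"
    orientation: str = "warmer"     # larger values mean "warmer" | "colder"
    _spline: CubicSpline | None = field(default=None, repr=False, compare=False)
    _warned: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.ndim != 1 or self.ages.size < 2:
            raise ValueError("curve needs at least two distinct ages")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if self.ages[0] < 0:
            raise ValueError("ages must be >= 0 Ma BP")
        if self.interpolation not in ("linear", "spline"):
            raise ValueError(f"unknown interpolation mode {self.interpolation!r}")
        if self.interpolation == "spline":
            # natural cubic spline (zero second derivative at the ends)
            self._spline = CubicSpline(self.ages, self.values, bc_type="natural")

    @property
    def max_age(self) -> float:
        return float(self.ages[-1])

    def at(self, t) -> float | np.ndarray:
        """Evaluate the proxy at age ``t`` (Ma BP); scalar in, scalar out."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("age must be >= 0 Ma BP")
        if np.any(t_arr > self.max_age) and not self._warned:
            warnings.warn(
                f"evaluating paleocurve beyond its last age ({self.max_age:g} Ma); "
                "continuing the oldest value", stacklevel=2)
            self._warned = True
        t_clip = np.clip(t_arr, self.ages[0], self.max_age)
        if self.interpolation == "linear":
            out = np.interp(t_clip, self.ages, self.values)
        else:
            out = self._spline(t_clip)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def is_flat(self, tol: float = 0.0) -> bool:
        return bool(np.ptp(self.values) <= tol)


def load_curve(path, interpolation: str = "linear",
               orientation: str = "warmer") -> PaleoCurve:
    """Load a two-column CSV (header ``age_ma,value``) into a PaleoCurve.

    Duplicate ages are collapsed by their mean value.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("curve CSV needs two columns: age_ma, value")
    df = df.iloc[:, :2]
    df.columns = ["age_ma", "value"]
    if df.isna().any().any():
        raise ValueError("curve CSV contains non-numeric or missing entries")
    df = df.astype(float).groupby("age_ma", as_index=False)["value"].mean()
    df = df.sort_values("age_ma")
    if df.shape[0] < 2:
        raise ValueError("curve needs at least two distinct ages")
    return PaleoCurve(ages=df["age_ma"].to_numpy(), values=df["value"].to_numpy(),
                      interpolation=interpolation, orientation=orientation)
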