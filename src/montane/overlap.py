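"""Sister-species overlap: Schoener's D across geography and ecology.

For every sister pair (cherry) in a dated phylogeny, the overlap of binary
occupancy vectors is computed along four dimensions: fine geography
(operational geographic units), coarse geography (major mountain regions
obtained by aggregating the units), bedrock type (calcareous vs siliceous)
and elevation belt (high vs mid). Presence/absence vectors are normalized
to proportions (uniform weight over occupied categories) before applying

    D(p, q) = 1 - 0.5 * sum_i |p_i - q_i|,

so D = 1 for identical ranges and D = 0 for disjoint ones. "No overlap" is
the exact event D = 0: with normalized rational vectors no tolerance is
needed, and a low proportion of zero-overlap pairs along a dimension is
read as little speciation along it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import Tree

__all__ = ["OccupancyTable", "schoener_d", "sister_overlap_table",
           "summarize_overlap"]

DIMENSIONS = ("fine_geo", "coarse_geo", "bedrock", "elevation")


def schoener_d(p, q) -> float:
    """Schoener's D of two occupancy vectors (normalized to sum 1 first)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("vectors must have equal length")
    sp, sq = p.sum(), q.sum()
    if sp <= 0 or sq <= 0:
        raise ValueError("occupancy vectors must have at least one positive entry")
    # for proportion vectors, 1 - 0.5 sum|p - q| == sum min(p, q); the min
    # form is exactly zero for disjoint supports, which the zero-overlap
    # summaries rely on
    return float(np.minimum(p / sp, q / sq).sum())


@dataclass
class OccupancyTable:
    """Per-species binary occupancy along the four overlap dimensions.

    ``units`` has one row per species and one 0/1 column per fine
    geographic unit; ``unit_to_region`` maps every unit column to a coarse
    region (covering each unit exactly once). ``bedrock`` and ``elevation``
    have two 0/1 columns each; a generalist ("both") species is (1, 1).
    """

    units: pd.DataFrame
    unit_to_region: dict[str, str]
    bedrock: pd.DataFrame
    elevation: pd.DataFrame
    regions: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        missing = set(self.units.columns) - set(self.unit_to_region)
        if missing:
            raise ValueError(f"units without a region assignment: {sorted(missing)}")
        for name, df in (("units", self.units), ("bedrock", self.bedrock),
                         ("elevation", self.elevation)):
            if ((df != 0) & (df != 1)).any().any():
                raise ValueError(f"{name} table must be binary")
            empty = df.index[df.sum(axis=1) == 0].tolist()
            if empty:
                raise ValueError(f"species with empty {name} occupancy: {empty}")
        region_names = sorted(set(self.unit_to_region.values()))
        agg = pd.DataFrame(0, index=self.units.index, columns=region_names)
        for unit in self.units.columns:
            region = self.unit_to_region[unit]
            agg[region] |= self.units[unit].astype(int)
        self.regions = agg

    @property
    def species(self) -> list[str]:
        return list(self.units.index)

    def vector(self, species: str, dimension: str) -> np.ndarray:
        table = {"fine_geo": self.units, "coarse_geo": self.regions,
                 "bedrock": self.bedrock, "elevation": self.elevation}[dimension]
        return table.loc[species].to_numpy(dtype=float)


def sister_overlap_table(tree: Tree, occ: OccupancyTable,
                         lineage: str = "clade") -> pd.DataFrame:
    """One overlap record per cherry: Schoener's D along each dimension.

    Pairs in which either species lacks occupancy data are dropped and
    reported in the ``missing`` column (flagged with NaN overlaps).
    """
    rows = []
    known = set(occ.species)
    for pair in tree.cherries():
        row = {"lineage": lineage, "species_a": pair.a, "species_b": pair.b,
               "pair_age": pair.age}
        absent = [s for s in (pair.a, pair.b) if s not in known]
        row["missing"] = ";".join(absent)
        for dim in DIMENSIONS:
            row[f"d_{dim}"] = (np.nan if absent else
                               schoener_d(occ.vector(pair.a, dim),
                                          occ.vector(pair.b, dim)))
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_overlap(records: pd.DataFrame, by_lineage: bool = False) -> pd.DataFrame:
    """Median D and proportion of zero-overlap pairs, per dimension.

    With ``by_lineage=True`` the summary is additionally broken down per
    lineage; pairs with missing data are excluded dimension-wise.
    """
    def _one(df: pd.DataFrame, label: str) -> list[dict]:
        out = []
        for dim in DIMENSIONS:
            col = df[f"d_{dim}"].dropna()
            out.append({"lineage": label, "dimension": dim,
                        "n_pairs": int(col.size),
                        "median_d": float(col.median()) if col.size else np.nan,
                        "prop_zero": float((col == 0.0).mean()) if col.size else np.nan})
        return out

    rows = _one(records, "all")
    if by_lineage:
        for label, sub in records.groupby("lineage"):
            rows.extend(_one(sub, str(label)))
    return pd.DataFrame(rows)
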