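"""Receptor-density spatial mapping.

A regional statistic map (one test statistic per cortical region, e.g. a
group contrast or a longitudinal slope statistic) is compared against
receptor / transporter density maps in two ways: Spearman rank correlation
per map (with BH-FDR across the map family), and dominance analysis — an
all-subsets OLS decomposition that apportions the full-model R² across
predictors.  The general dominance weight of a predictor is its average
incremental R² over all subset sizes; the weights are non-negative and sum
exactly to the full-model R².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .io import ReceptorTable, ValidationError
from .inference import fdr_adjust

__all__ = ["MappingResult", "spearman_map_correlation", "dominance_analysis"]

MAX_DOMINANCE_PREDICTORS = 12  # all-subsets regression is 2^p


@dataclass
class MappingResult:
    correlations: pd.DataFrame | None = None  # map, rho, p_raw, p_fdr
    dominance: dict[str, float] | None = None
    total_r2: float | None = None
    dominance_on_ranks: bool = False
    family_id: str = "receptor_maps"


def _aligned(stat_map: pd.Series, receptors: ReceptorTable) -> pd.DataFrame:
    missing = set(stat_map.index) - set(receptors.frame.index)
    if missing:
        raise ValidationError(
            f"receptor table missing regions of the stat map: {sorted(missing)[:5]}"
        )
    frame = receptors.frame.loc[stat_map.index].copy()
    if not np.isfinite(stat_map.to_numpy()).all():
        raise ValidationError("stat map contains non-finite values")
    return frame


def spearman_map_correlation(
    stat_map: pd.Series,
    receptors: ReceptorTable,
    family_id: str = "receptor_maps",
) -> MappingResult:
    """Spearman rho (average-rank ties, two-sided t-approximation p) per map.

    FDR adjustment is applied across the receptor-map family.
    """
    frame = _aligned(stat_map, receptors)
    y = stat_map.to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise ValidationError("stat map is constant: correlation undefined")
    rows = []
    for name in frame.columns:
        x = frame[name].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            raise ValidationError(f"receptor map {name!r} is constant")
        rho, p = spearmanr(y, x)
        rows.append({"map": name, "rho": float(rho), "p_raw": float(p)})
    table = pd.DataFrame(rows)
    table["p_fdr"] = fdr_adjust(table["p_raw"].to_numpy(), family_id=family_id)
    return MappingResult(correlations=table, family_id=family_id)


def _r2_all_subsets(x: np.ndarray, y: np.ndarray) -> dict[frozenset, float]:
    """R² of the OLS fit (with intercept) for every predictor subset."""
    n, p = x.shape
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sst = float(yc @ yc)
    r2: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            xs = xc[:, subset]
            beta, *_ = np.linalg.lstsq(xs, yc, rcond=None)
            resid = yc - xs @ beta
            r2[frozenset(subset)] = 1.0 - float(resid @ resid) / sst
    return r2


def dominance_analysis(
    stat_map: pd.Series,
    receptors: ReceptorTable,
    predictor_subset: list[str] | None = None,
    on_ranks: bool = False,
    family_id: str = "receptor_maps",
) -> MappingResult:
    """General dominance decomposition of the stat map on receptor maps.

    The weight of predictor j is the mean over subset sizes k of the mean
    incremental R² from adding j to size-k subsets of the other predictors.
    ``on_ranks`` fits on average ranks instead of raw values (rank-based
    variant of the same decomposition).
    """
    frame = _aligned(stat_map, receptors)
    names = predictor_subset or list(frame.columns)
    unknown = set(names) - set(frame.columns)
    if unknown:
        raise ValidationError(f"unknown receptor maps: {sorted(unknown)}")
    p = len(names)
    if p == 0:
        raise ValidationError("no predictors selected")
    if p > MAX_DOMINANCE_PREDICTORS:
        raise ValidationError(
            f"{p} predictors exceed the all-subsets limit of "
            f"{MAX_DOMINANCE_PREDICTORS}"
        )
    x = frame[names].to_numpy(dtype=float)
    y = stat_map.to_numpy(dtype=float)
    if on_ranks:
        x = np.column_stack([rankdata(x[:, j]) for j in range(p)])
        y = rankdata(y)
    if y.std() == 0:
        raise ValidationError("stat map is constant")
    xc = x - x.mean(axis=0)
    if np.linalg.matrix_rank(xc) < p:
        # name a minimal collinear pair if one exists
        corr = np.corrcoef(xc, rowvar=False)
        for i in range(p):
            for j in range(i + 1, p):
                if abs(corr[i, j]) > 1 - 1e-10:
                    raise ValidationError(
                        f"rank-deficient design: maps {names[i]!r} and "
                        f"{names[j]!r} are collinear"
                    )
        raise ValidationError("rank-deficient full design matrix")
    r2 = _r2_all_subsets(x, y)
    weights: dict[str, float] = {}
    others = list(range(p))
    for j in range(p):
        rest = [m for m in others if m != j]
        size_means = []
        for size in range(0, p):
            increments = [
                r2[frozenset(s) | {j}] - r2[frozenset(s)]
                for s in combinations(rest, size)
            ]
            size_means.append(float(np.mean(increments)))
        weights[names[j]] = float(np.mean(size_means))
    total = r2[frozenset(range(p))]
    return MappingResult(
        dominance=weights,
        total_r2=float(total),
        dominance_on_ranks=on_ranks,
        family_id=family_id,
    )
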