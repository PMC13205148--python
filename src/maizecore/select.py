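"""Core-collection selection: MNND uniqueness, CV-weighted TOPSIS, composite.

Each line receives a genetic-uniqueness score (MNND — mean genetic distance
to the other lines, or the mean over its k nearest neighbours) and a
phenotypic superiority score (TOPSIS D value) computed from direction-coded,
CV-weighted BLUPs: grain traits count as positive indicators, plant
architecture and tassel traits as negative ones. Selection is two-stage:
the top ``n_stage1`` lines by D, then the top ``n_final`` by a weighted
composite of min-max-scaled D (80%) and MNND (20%) within that subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceMatrix

#: Default indicator directions: grain traits are improved upward, plant
#: architecture and tassel traits downward (compact, low-ear, modest tassel).
DEFAULT_DIRECTIONS = {
    "KL": +1, "KW": +1, "LWR": +1,
    "PH": -1, "EH": -1, "EPR": -1,
    "TPN": -1, "TBL": -1, "LUL": -1, "LUT": -1,
}


@dataclass
class TraitConfig:
    directions: dict[str, int]
    weights: pd.Series            # > 0, sums to 1

    def __post_init__(self) -> None:
        self.weights = pd.Series(self.weights, dtype=float)
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")
        s = self.weights.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        for t in self.weights.index:
            if t not in self.directions:
                raise ValueError(f"no direction for trait {t!r}")

    @classmethod
    def from_cv(cls, blups: pd.DataFrame,
                directions: dict[str, int] | None = None) -> "TraitConfig":
        """CV-derived weights: w_j = CV_j / sum CV (CV = SD/|mean| x 100)."""
        directions = dict(directions or DEFAULT_DIRECTIONS)
        cv = blups.std(ddof=1) / blups.mean().abs() * 100.0
        return cls(directions=directions, weights=cv / cv.sum())


def mnnd_scores(dist: DistanceMatrix, mode: str = "mean-all", k: int = 5) -> pd.Series:
    """Per-line genetic-uniqueness score from a distance matrix.

    ``"mean-all"``: mean distance to every other line. ``"nearest-k"``: mean
    of the k smallest off-diagonal distances.
    """
    if dist.n < 2:
        raise ValueError("need >= 2 lines")
    D = dist.values
    n = dist.n
    off = D + np.diag(np.full(n, np.nan))
    if mode == "mean-all":
        vals = np.nanmean(off, axis=1)
    elif mode == "nearest-k":
        kk = min(k, n - 1)
        sorted_rows = np.sort(off, axis=1)[:, :kk]  # NaN sorts last
        vals = sorted_rows.mean(axis=1)
    else:
        raise ValueError(f"unknown MNND mode {mode!r}")
    return pd.Series(vals, index=dist.labels, name="MNND")


def topsis_scores(
    blups: pd.DataFrame,
    config: TraitConfig,
    standardization: str = "minmax",
) -> pd.DataFrame:
    """TOPSIS D value per line from direction-coded standardized traits.

    Steps: (1) direction-coded standardization — min-max by default
    (positive x' = (x-min)/(max-min), negative x' = (max-x)/(max-min)); the
    ``"vector"`` dialect divides by the column Euclidean norm and flips via
    the ideal-point choice; (2) multiply by weights; (3) ideal A+ = column
    max, anti-ideal A- = column min; (4) Euclidean d+, d-; (5)
    D = d-/(d+ + d-). Returns a DataFrame with D, d_plus, d_minus.
    """
    traits = [t for t in blups.columns if t in config.weights.index]
    X = blups[traits].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("trait matrix must be complete")
    if X.shape[0] < 2:
        raise ValueError("need >= 2 lines")
    rng_ = X.max(axis=0) - X.min(axis=0)
    keep = rng_ > 0
    if not keep.all():
        dropped = [t for t, k in zip(traits, keep) if not k]
        warnings.warn(f"constant traits excluded, weights renormalized: {dropped}",
                      stacklevel=2)
        traits = [t for t, k in zip(traits, keep) if k]
        X = X[:, keep]
        rng_ = rng_[keep]
    w = config.weights[traits]
    w = (w / w.sum()).to_numpy()
    sign = np.array([config.directions[t] for t in traits], dtype=float)

    if standardization == "minmax":
        Xp = (X - X.min(axis=0)) / rng_
        Xp = np.where(sign > 0, Xp, 1.0 - Xp)
        V = Xp * w
        ideal = V.max(axis=0)
        anti = V.min(axis=0)
    elif standardization == "vector":
        norm = np.sqrt((X ** 2).sum(axis=0))
        V = X / norm * w
        ideal = np.where(sign > 0, V.max(axis=0), V.min(axis=0))
        anti = np.where(sign > 0, V.min(axis=0), V.max(axis=0))
    else:
        raise ValueError(f"unknown standardization {standardization!r}")

    d_plus = np.sqrt(((V - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((V - anti) ** 2).sum(axis=1))
    denom = d_plus + d_minus
    denom[denom == 0] = 1.0
    D = d_minus / denom
    return pd.DataFrame(
        {"D": D, "d_plus": d_plus, "d_minus": d_minus},
        index=blups.index,
    )


def _minmax(x: pd.Series) -> pd.Series:
    rng_ = x.max() - x.min()
    if rng_ == 0:
        return pd.Series(0.0, index=x.index)
    return (x - x.min()) / rng_


@dataclass
class SelectionResult:
    scores: pd.DataFrame          # all lines: D, MNND, ranks, flags
    stage1: pd.DataFrame          # top-n_stage1 set with composite scores
    final: pd.DataFrame           # top-n_final by composite
    w_topsis: float
    w_mnnd: float


def composite_select(
    topsis: pd.DataFrame,
    mnnd: pd.Series,
    w_topsis: float = 0.8,
    w_mnnd: float = 0.2,
    n_stage1: int = 50,
    n_final: int = 30,
) -> SelectionResult:
    """Two-stage selection: top-D subset, then composite-ranked core set.

    Within the stage-1 set, D and MNND are min-max scaled to [0,1] (their
    raw scales are incommensurate) and combined as
    composite = w_topsis * D~ + w_mnnd * M~. Ties break toward higher MNND,
    then label order.
    """
    if abs(w_topsis + w_mnnd - 1.0) > 1e-9:
        raise ValueError("w_topsis + w_mnnd must equal 1")
    df = topsis.copy()
    df["MNND"] = mnnd.reindex(df.index)
    n = len(df)
    if not (n >= n_stage1 >= n_final):
        raise ValueError("need n >= n_stage1 >= n_final")
    df["_label"] = df.index.astype(str)
    df = df.sort_values(["D", "MNND", "_label"], ascending=[False, False, True])
    df["d_rank"] = np.arange(1, n + 1)
    df["selected_stage1"] = df["d_rank"] <= n_stage1

    stage1 = df[df["selected_stage1"]].copy()
    stage1["D_scaled"] = _minmax(stage1["D"])
    stage1["MNND_scaled"] = _minmax(stage1["MNND"])
    stage1["composite"] = w_topsis * stage1["D_scaled"] + w_mnnd * stage1["MNND_scaled"]
    stage1 = stage1.sort_values(["composite", "MNND", "_label"],
                                ascending=[False, False, True])
    stage1["composite_rank"] = np.arange(1, len(stage1) + 1)
    stage1["selected_final"] = stage1["composite_rank"] <= n_final
    final = stage1[stage1["selected_final"]].copy()

    df["selected_final"] = df.index.isin(final.index)
    for frame in (df, stage1, final):
        frame.drop(columns=["_label"], inplace=True)
    return SelectionResult(scores=df, stage1=stage1, final=final,
                           w_topsis=w_topsis, w_mnnd=w_mnnd)


def core_report(
    selection: SelectionResult,
    blups: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
) -> dict:
    """Per-line core-set table plus composition summary.

    The table carries D, MNND, rank by D value (strictly decreasing D), the
    trait values, and any annotation columns (type, clade, ancestry); the
    summary counts lines by those categories, gives the D range, and flags
    per-trait position relative to the population mean.
    """
    final = selection.final.sort_values("D", ascending=False).copy()
    table = final[["D", "MNND"]].copy()
    table["rank"] = np.arange(1, len(table) + 1)
    table = table.join(blups, how="left")
    if annotations is not None:
        table = table.join(annotations, how="left")

    pop_mean = blups.mean()
    above = (table[blups.columns] > pop_mean).sum()
    summary = {
        "n_selected": int(len(table)),
        "d_min": float(table["D"].min()),
        "d_max": float(table["D"].max()),
        "d_range": float(table["D"].max() - table["D"].min()),
        "mnnd_min": float(table["MNND"].min()),
        "mnnd_max": float(table["MNND"].max()),
        "mnnd_range": float(table["MNND"].max() - table["MNND"].min()),
        "n_above_population_mean": {t: int(above[t]) for t in blups.columns},
    }
    if annotations is not None:
        for col in annotations.columns:
            counts = table[col].value_counts(dropna=True)
            summary[f"by_{col}"] = {str(k): int(v) for k, v in counts.items()}
    return {"table": table, "summary": summary}
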