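"""Prognostic marker-combination discovery and coexpression structure.

Combination values come in two modes: ``colocalization`` (the log density of
the co-label column the quantification stage produced) and ``additive`` (the
sum of the member markers' log values, the route available to sequential
single-stain assays). Every enumerated combination is dichotomized at
mean±SEM and scored by log-rank; PCA on z-scored log values defines
coexpression groups whose per-unit scores can themselves be survival-tested.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations as iter_combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from tilquant.cohort import dichotomize
from tilquant.errors import ConfigError, DegenerateTestError
from tilquant.stats import SurvTestResult, logrank_test
from tilquant.syndata import combination_key

MAX_COMBO_SIZE = 4


@dataclass
class CombinationSpec:
    markers: tuple[str, ...]
    mode: str = "colocalization"  # or "additive"
    anchor: str | None = None

    def __post_init__(self) -> None:
        members = self.all_markers
        if len(set(members)) != len(members):
            raise ConfigError(f"duplicate markers in combination {members}")
        if self.mode not in {"colocalization", "additive"}:
            raise ConfigError(f"unknown combination mode {self.mode!r}")

    @property
    def all_markers(self) -> tuple[str, ...]:
        extra = (self.anchor,) if self.anchor and self.anchor not in self.markers else ()
        return tuple(self.markers) + extra

    @property
    def key(self) -> str:
        return combination_key(self.all_markers)


@dataclass
class CoexGroup:
    """One principal component read as a coexpression group."""

    component: int  # 0-based PC index
    members: list[str]
    loadings: pd.Series
    scores: pd.Series  # per analysis unit, orientation-corrected
    orientation: int  # +1 or -1 applied to the raw PCA scores
    variance_ratio: float


def combination_value(matrix: pd.DataFrame, spec: CombinationSpec) -> pd.Series:
    """Per-unit value vector for one combination."""
    markers = spec.all_markers
    if spec.mode == "additive":
        missing = [m for m in markers if m not in matrix.columns]
        if missing:
            raise ConfigError(f"matrix lacks columns {missing}")
        return matrix[list(markers)].sum(axis=1).rename(spec.key)
    key = spec.key
    if key not in matrix.columns:
        raise ConfigError(
            f"matrix lacks co-label column {key!r}: re-run quantification with "
            f"combinations including {tuple(sorted(markers))}"
        )
    return matrix[key].rename(key)


def global_score(matrix: pd.DataFrame, icp_set) -> pd.DataFrame:
    """Per-patient global ICP scores over a marker set.

    ``sum_score`` sums the (log) values of the set; ``count_score`` counts how
    many set members exceed their own cohort mean — the "number of ICPs per
    patient" summary.
    """
    icps = list(icp_set)
    if not icps:
        raise ConfigError("empty ICP set")
    missing = [m for m in icps if m not in matrix.columns]
    if missing:
        raise ConfigError(f"matrix lacks columns {missing}")
    sub = matrix[icps].astype(float)
    means = sub.mean(axis=0)
    return pd.DataFrame(
        {"sum_score": sub.sum(axis=1), "count_score": (sub > means).sum(axis=1)}
    )


def score_combination(
    values: pd.Series, months: pd.Series, events: pd.Series
) -> tuple[SurvTestResult, object]:
    """Dichotomize one value vector at mean±SEM and log-rank hi vs lo."""
    d = dichotomize(values)
    hi = d.labels == "hi"
    lo = d.labels == "lo"
    if hi.sum() == 0 or lo.sum() == 0:
        raise DegenerateTestError("dichotomization produced an empty group")
    res = logrank_test(months[hi], events[hi], months[lo], events[lo])
    return res, d


def rank_combinations(
    matrix: pd.DataFrame,
    months: pd.Series,
    events: pd.Series,
    candidates,
    sizes=(2, 3),
    anchor: str | None = None,
    mode: str = "colocalization",
    bh: bool = False,
) -> pd.DataFrame:
    """Exhaustively score marker combinations and rank them by log-rank p.

    Every combination of the candidate markers at the requested sizes (plus
    the anchor, when given) is valued, dichotomized at mean±SEM and log-rank
    tested; the report is sorted by p ascending with ties broken by |log HR|
    descending. ``bh=True`` adds Benjamini–Hochberg q-values over the scanned
    family. Degenerate combinations are kept in the report with a reason and
    NaN statistics.
    """
    candidates = [c for c in candidates if c != anchor]
    size_list = sorted(set(sizes))
    if max(size_list) + (1 if anchor else 0) > MAX_COMBO_SIZE:
        raise ConfigError(f"combination size capped at {MAX_COMBO_SIZE}")
    rows = []
    for k in size_list:
        for markers in iter_combinations(sorted(candidates), k):
            spec = CombinationSpec(markers=markers, mode=mode, anchor=anchor)
            row = {"combination": spec.key, "size": len(spec.all_markers), "mode": mode}
            try:
                vals = combination_value(matrix, spec)
                res, d = score_combination(vals, months, events)
            except (DegenerateTestError, ConfigError) as exc:
                row.update(
                    {"n_hi": np.nan, "n_lo": np.nan, "chi2": np.nan, "p": np.nan,
                     "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                     "skipped": str(exc)}
                )
            else:
                row.update(
                    {"n_hi": res.n_hi, "n_lo": res.n_lo, "chi2": res.chi2, "p": res.p,
                     "hr": res.hr, "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                     "skipped": ""}
                )
            rows.append(row)
    report = pd.DataFrame(rows)
    report["abs_log_hr"] = np.abs(np.log(report["hr"].where(report["hr"] > 0)))
    report = report.sort_values(
        ["p", "abs_log_hr"], ascending=[True, False], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    if bh:
        tested = report["p"].notna()
        m = int(tested.sum())
        p = report.loc[tested, "p"].to_numpy()
        order = np.argsort(p)
        q = np.empty_like(p)
        q[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        report.loc[tested, "q"] = np.clip(np.maximum(q, p), None, 1.0)
    return report.drop(columns=["abs_log_hr"])


def correlogram(matrix: pd.DataFrame, marker_set=None):
    """Pairwise Pearson matrix with average-linkage ordering on 1 − r.

    Returns (correlation DataFrame reordered, leaf order list, top pair).
    Constant columns are dropped with a warning.
    """
    cols = list(marker_set) if marker_set is not None else list(matrix.columns)
    if len(cols) < 3:
        raise ValueError("need >= 3 markers")
    sub = matrix[cols].astype(float)
    constant = [c for c in cols if sub[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(f"dropping constant columns: {constant}")
        sub = sub.drop(columns=constant)
    corr = sub.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    order = leaves_list(linkage(squareform(dist, checks=False), method="average"))
    ordered = corr.iloc[order, order]
    off = corr.where(~np.eye(len(corr), dtype=bool))
    top_pair = off.stack().idxmax()
    return ordered, [corr.columns[i] for i in order], tuple(sorted(top_pair))


def pca_groups(
    matrix: pd.DataFrame,
    marker_set=None,
    n_components: int = 2,
    membership_frac: float = 0.5,
) -> list[CoexGroup]:
    """Coexpression groups from PCA of column-standardised log values.

    Each component's group contains the markers whose |loading| is at least
    ``membership_frac`` of that component's max |loading|. Score orientation
    is flipped so that each PC score correlates positively with the mean
    expression of its member markers (PCA signs are arbitrary).
    """
    cols = list(marker_set) if marker_set is not None else list(matrix.columns)
    sub = matrix[cols].astype(float).dropna()
    sd = sub.std(ddof=0)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        warnings.warn(f"dropping zero-variance columns: {degenerate}")
        sub = sub.drop(columns=degenerate)
    if sub.shape[1] < 2:
        raise DegenerateTestError("need >= 2 non-degenerate markers for PCA")
    z = (sub - sub.mean()) / sub.std(ddof=0)
    pca = PCA(n_components=min(n_components, z.shape[1]))
    raw_scores = pca.fit_transform(z.to_numpy())
    groups: list[CoexGroup] = []
    for i in range(pca.n_components_):
        load = pd.Series(pca.components_[i], index=z.columns)
        members = load.index[np.abs(load) >= membership_frac * np.abs(load).max()].tolist()
        scores = pd.Series(raw_scores[:, i], index=z.index)
        mean_expr = z[members].mean(axis=1)
        sign = 1
        if len(members) and float(np.cov(scores, mean_expr)[0, 1]) < 0:
            sign = -1
        groups.append(
            CoexGroup(
                component=i,
                members=sorted(members),
                loadings=load * sign,
                scores=scores * sign,
                orientation=sign,
                variance_ratio=float(pca.explained_variance_ratio_[i]),
            )
        )
    return groups


def pc_survival(scores: pd.Series, months: pd.Series, events: pd.Series) -> SurvTestResult:
    """mean±SEM dichotomization of PC scores followed by log-rank hi vs lo."""
    aligned = pd.concat({"s": scores, "m": months, "e": events}, axis=1).dropna()
    res, _ = score_combination(aligned["s"], aligned["m"], aligned["e"])
    return res
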