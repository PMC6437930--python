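"""Patient-level assembly: aggregation of core records, mean±SEM
dichotomization, and ROC validation of cutoffs.

Two aggregation conventions are supported, matching the two analysis routes
of replicate-core TMA studies: ``average`` (one row per patient, the
arithmetic mean of its cores' log values) and ``per_core`` (one row per
core, each carrying its patient's survival data — replicate cores are not
averaged, exposing inter-core variability).

The hi/lo rule dichotomizes each marker at the cohort mean ± SEM: values
strictly above mean+SEM are "hi", strictly below mean−SEM are "lo", and the
mid-band is excluded, which is why classified group sizes need not sum to
the cohort size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from tilquant.errors import ConfigError, DegenerateTestError


@dataclass
class DichotomyResult:
    """hi/lo/excluded assignment for one marker."""

    labels: pd.Series  # unit_id -> {"hi", "lo", "excluded"}
    mean: float
    sem: float

    @property
    def cutoff_hi(self) -> float:
        return self.mean + self.sem

    @property
    def cutoff_lo(self) -> float:
        return self.mean - self.sem

    @property
    def n_hi(self) -> int:
        return int((self.labels == "hi").sum())

    @property
    def n_lo(self) -> int:
        return int((self.labels == "lo").sum())

    @property
    def n_excluded(self) -> int:
        return int((self.labels == "excluded").sum())


def aggregate(
    quant: pd.DataFrame,
    core_map: pd.DataFrame,
    method: str = "average",
    value_col: str = "log_value",
) -> pd.DataFrame:
    """Pivot tidy per-core records into a units × combination matrix.

    ``method="average"`` returns one row per patient (mean over its cores,
    missing cores dropped from the mean); ``method="per_core"`` returns one
    row per core with a ``patient_id`` column. The unit id is the index.
    """
    if method not in {"average", "per_core"}:
        raise ValueError(f"unknown aggregation method {method!r}")
    mapping = core_map.set_index("core_id")["patient_id"]
    unmapped = sorted(set(quant["core_id"]) - set(mapping.index))
    if unmapped:
        raise ConfigError(f"cores with no patient mapping: {unmapped}")
    df = quant.copy()
    df["patient_id"] = df["core_id"].map(mapping)
    wide = df.pivot_table(
        index=["patient_id", "core_id"], columns="combination_key",
        values=value_col, aggfunc="first",
    )
    if method == "per_core":
        out = wide.reset_index().set_index("core_id")
        out.columns.name = None
        return out
    out = wide.groupby(level="patient_id").mean()
    out.columns.name = None
    return out


def attach_survival(matrix: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Join months/event (and covariates) onto an aggregated matrix.

    Works for both aggregation methods: a ``patient_id`` column is used when
    present (per-core rows), otherwise the index is the patient id.
    """
    clin = clinical.set_index("patient_id")
    if "patient_id" in matrix.columns:
        joined = matrix.join(clin, on="patient_id")
    else:
        joined = matrix.join(clin)
    missing = joined.index[joined["months"].isna()]
    if len(missing):
        raise ConfigError(f"units with no clinical record: {sorted(missing)}")
    return joined


def dichotomize(values: pd.Series, min_n: int = 3) -> DichotomyResult:
    """Three-way mean±SEM split: hi (> mean+SEM), lo (< mean−SEM), excluded.

    SEM uses the sample SD (n−1 denominator). Values on the band boundaries
    are excluded (strict inequalities). Missing values are dropped before the
    cutoffs are computed and come back labelled "excluded".
    """
    v = values.dropna().astype(float)
    if len(v) < min_n:
        raise DegenerateTestError(f"need >= {min_n} non-missing values, got {len(v)}")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(len(v)))
    if sem == 0.0:
        warnings.warn("all values identical: SEM is 0 and every unit is excluded")
    labels = pd.Series("excluded", index=values.index, dtype=object)
    labels[values > mean + sem] = "hi"
    labels[values < mean - sem] = "lo"
    return DichotomyResult(labels=labels, mean=mean, sem=sem)


def roc_validate(
    values: pd.Series,
    outcome: pd.Series,
    cutoffs: tuple[float, float] | None = None,
) -> dict:
    """Validate dichotomization cutoffs against the death outcome by ROC.

    AUC is the trapezoidal area under the full threshold sweep (equivalently
    the pairwise concordance probability with ties counted 1/2). Sensitivity
    and specificity are reported at each supplied cutoff (prediction rule:
    value > cutoff calls a death) alongside the Youden-J-maximising cutoff.
    """
    mask = values.notna() & outcome.notna()
    v = values[mask].astype(float).to_numpy()
    y = outcome[mask].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise DegenerateTestError("ROC undefined: outcome has a single class")
    auc = float(roc_auc_score(y, v))
    fpr, tpr, thr = roc_curve(y, v)
    youden = thr[np.argmax(tpr - fpr)]
    out = {"auc": auc, "youden_cutoff": float(youden), "n": int(len(v)), "at_cutoff": {}}
    for c in cutoffs or ():
        pred = v > c
        tp = int((pred & (y == 1)).sum())
        fn = int((~pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        fp = int((pred & (y == 0)).sum())
        out["at_cutoff"][float(c)] = {
            "sensitivity": tp / (tp + fn),
            "specificity": tn / (tn + fp),
        }
    return out
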