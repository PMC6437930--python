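"""Four-criterion refinement of ICP-interacting proteins.

Works from a database-agnostic interaction table (protein_a, protein_b,
evidence, tissues, sources) and a per-protein annotation table
(os_association in {positive, negative, none}; tumor_expression in
{increased, decreased, unchanged}). A candidate interactor is retained when
it (1) has at least one experimentally validated edge to an ICP,
(2) interacts with at least two distinct ICPs, (3) is associated with
overall survival, and (4) has at least one ICP edge supported in the
required tissue (default "lung"). ICP–ICP edges count toward redundancy.
"""

from __future__ import annotations

import warnings

import pandas as pd

from tilquant.errors import ConfigError

OS_LEVELS = {"positive", "negative", "none"}
EXPR_LEVELS = {"increased", "decreased", "unchanged"}
INTERACTION_COLUMNS = ["protein_a", "protein_b", "evidence", "tissues", "sources"]


def _split_tags(value) -> set[str]:
    if pd.isna(value) or value == "":
        return set()
    return {t.strip() for t in str(value).split(";") if t.strip()}


def _icp_edges(interactions: pd.DataFrame, icp_set: set[str]) -> pd.DataFrame:
    """Long table of (protein, icp, evidence, tissues) for edges touching an ICP."""
    rows = []
    for rec in interactions.itertuples(index=False):
        a, b = sorted((rec.protein_a, rec.protein_b))
        if a == b:
            continue
        for prot, other in ((a, b), (b, a)):
            if other in icp_set:
                rows.append(
                    {"protein": prot, "icp": other, "evidence": rec.evidence,
                     "tissues": _split_tags(getattr(rec, "tissues", ""))}
                )
    return pd.DataFrame(rows, columns=["protein", "icp", "evidence", "tissues"])


def refine_interactors(
    interactions: pd.DataFrame,
    annotations: pd.DataFrame,
    icp_set,
    tissue: str = "lung",
) -> pd.DataFrame:
    """Apply the four refinement criteria; returns per-protein audit flags.

    One row per candidate protein (any protein sharing an edge with an ICP)
    with boolean columns ``c1_experimental``, ``c2_redundant``, ``c3_os``,
    ``c4_tissue`` and ``pass_all``. Proteins missing from the annotation
    table are warned about and fail the OS criterion.
    """
    icps = set(icp_set)
    if not icps:
        raise ConfigError("icp_set must be non-empty")
    ann = annotations.set_index("protein")
    bad_os = set(ann["os_association"]) - OS_LEVELS
    if bad_os:
        raise ConfigError(f"unknown os_association values: {sorted(bad_os)}")

    edges = _icp_edges(interactions, icps)
    if edges.empty:
        return pd.DataFrame(
            columns=["protein", "n_icp_partners", "c1_experimental", "c2_redundant",
                     "c3_os", "c4_tissue", "pass_all"]
        )
    rows = []
    unannotated = []
    for prot, grp in edges.groupby("protein"):
        c1 = bool((grp["evidence"] == "experimental").any())
        partners = set(grp["icp"])
        c2 = len(partners) >= 2
        if prot in ann.index:
            c3 = ann.loc[prot, "os_association"] != "none"
        else:
            unannotated.append(prot)
            c3 = False
        c4 = bool(grp["tissues"].apply(lambda s: tissue in s).any())
        rows.append(
            {"protein": prot, "n_icp_partners": len(partners), "c1_experimental": c1,
             "c2_redundant": c2, "c3_os": c3, "c4_tissue": c4,
             "pass_all": c1 and c2 and c3 and c4}
        )
    if unannotated:
        warnings.warn(f"proteins without annotation treated as unannotated: {sorted(unannotated)}")
    return pd.DataFrame(rows).sort_values("protein").reset_index(drop=True)


def quadrant_summary(
    refined: pd.DataFrame,
    annotations: pd.DataFrame,
    interactions: pd.DataFrame | None = None,
    icp_set=None,
) -> dict:
    """Expression-by-outcome quadrant counts over the refined interactors.

    Returns the (tumor_expression × os_association) contingency with counts
    and fractions of the refined set, plus — when the interaction table and
    ICP set are supplied — each ICP's degree (number of distinct refined
    interactors), ranked descending.
    """
    passed = refined[refined["pass_all"]] if "pass_all" in refined.columns else refined
    if passed.empty:
        raise ValueError("refined table is empty")
    ann = annotations.set_index("protein")
    sub = ann.reindex(passed["protein"])
    counts = (
        sub.groupby(["tumor_expression", "os_association"], dropna=False)
        .size().rename("count").reset_index()
    )
    total = int(counts["count"].sum())
    counts["fraction_pct"] = 100.0 * counts["count"] / total
    out = {"counts": counts, "total": total}

    os_counts = sub["os_association"].value_counts()
    out["positive_os_pct"] = 100.0 * os_counts.get("positive", 0) / total
    pos = sub[sub["os_association"] == "positive"]
    out["increased_given_positive_pct"] = (
        100.0 * (pos["tumor_expression"] == "increased").sum() / len(pos) if len(pos) else float("nan")
    )

    if interactions is not None and icp_set is not None:
        edges = _icp_edges(interactions, set(icp_set))
        edges = edges[edges["protein"].isin(set(passed["protein"]))]
        degree = (
            edges.groupby("icp")["protein"].nunique().rename("degree")
            .sort_values(ascending=False).reset_index()
        )
        out["icp_degree"] = degree
    return out


def read_interactions_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"interactions TSV lacks columns {missing}")
    return df


def read_annotations_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("protein", "os_association", "tumor_expression"):
        if col not in df.columns:
            raise ConfigError(f"annotations TSV lacks column {col!r}")
    return df
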