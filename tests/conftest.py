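import numpy as np
import pandas as pd
import pytest

from tilquant.syndata import ImageSpec

SMALL_PANEL = {"CD45": 1.0, "CD3": 0.5, "TIM-3": 0.3, "CD20": 0.15}


def small_spec(**overrides) -> ImageSpec:
    """A 0.15 mm core with ~50 cells: fast enough for per-test rendering."""
    kw = dict(
        core_diameter_um=150.0,
        cells_per_core_mean=50.0,
        cells_per_core_sd=8.0,
        marker_prevalence=dict(SMALL_PANEL),
        coexpression={("CD3", "TIM-3"): 0.15},
    )
    kw.update(overrides)
    return ImageSpec(**kw)


def noiseless_spec(**overrides) -> ImageSpec:
    kw = dict(intensity_bg=(0.0, 0.0), bleedthrough=0.0)
    kw.update(overrides)
    return small_spec(**kw)


@pytest.fixture(scope="session")
def small_core():
    """One rendered small core with its ground truth (default noise)."""
    from tilquant.syndata import generate_core_image

    spec = small_spec()
    image, cells, mask = generate_core_image(spec, seed=7, core_id="t0")
    return spec, image, cells, mask


@pytest.fixture(scope="session")
def noiseless_core():
    from tilquant.syndata import generate_core_image

    spec = noiseless_spec()
    image, cells, mask = generate_core_image(spec, seed=11, core_id="t1")
    return spec, image, cells, mask


def interactor_fixture():
    """Ten interaction rows + annotations with hand-set criterion flags.

    Hand enumeration of the four criteria (experimental ICP edge, >=2 distinct
    ICP partners, OS association, lung-tissue ICP edge) over this table gives
    refined set {A, B}:

    - A: experimental edges to ICP1 (lung) and ICP2      -> passes all
    - B: experimental edges to ICP1 and ICP2 (lung)      -> passes all
    - C: experimental edge to ICP1 only                  -> fails redundancy
    - D: predicted edges to ICP1 and ICP2                -> fails experimental
    - E: experimental ICP1 + ICP2 edges, os none         -> fails OS
    - F: experimental ICP1 + ICP2 edges, no lung tag     -> fails tissue
    - G: edge to non-ICP only                            -> not a candidate
    """
    interactions = pd.DataFrame(
        [
            ("A", "ICP1", "experimental", "lung;liver", "s1"),
            ("A", "ICP2", "experimental", "", "s2"),
            ("B", "ICP1", "experimental", "", "s3"),
            ("ICP2", "B", "experimental", "lung", "s4"),
            ("C", "ICP1", "experimental", "lung", "s5"),
            ("D", "ICP1", "predicted", "lung", "s6"),
            ("D", "ICP2", "predicted", "lung", "s7"),
            ("E", "ICP1", "experimental", "lung", "s8"),
            ("E", "ICP2", "experimental", "lung", "s9"),
            ("F", "ICP1", "experimental", "brain", "s10"),
            ("F", "ICP2", "experimental", "", "s11"),
            ("G", "X1", "experimental", "lung", "s12"),
        ],
        columns=["protein_a", "protein_b", "evidence", "tissues", "sources"],
    )
    annotations = pd.DataFrame(
        [
            ("A", "positive", "increased"),
            ("B", "negative", "increased"),
            ("C", "positive", "decreased"),
            ("D", "positive", "increased"),
            ("E", "none", "increased"),
            ("F", "positive", "unchanged"),
            ("ICP1", "positive", "increased"),
            ("ICP2", "positive", "increased"),
        ],
        columns=["protein", "os_association", "tumor_expression"],
    )
    return interactions, annotations, ["ICP1", "ICP2"], {"A", "B"}


def match_centroids(true_xy: np.ndarray, det_xy: np.ndarray, tol_px: float = 5.0):
    """Greedy nearest matching; returns (sensitivity, precision)."""
    from scipy.spatial import cKDTree

    if len(det_xy) == 0:
        return 0.0, 0.0
    tree = cKDTree(det_xy)
    d, idx = tree.query(true_xy, k=1)
    hit = d <= tol_px
    sens = hit.mean()
    prec = len(set(idx[hit])) / len(det_xy)
    return float(sens), float(prec)
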