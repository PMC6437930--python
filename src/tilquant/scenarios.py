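"""Named simulation scenarios: the study conditions exercised by the test
suite and the reproduction script.

Centralising them here keeps every consumer (unit tests, acceptance checks,
worked examples) on identical generator settings. The panel emulates a
DAPI + CD45 + CD3 + ICP multiplex design on immune-enriched cores; subset
prevalences for CD3 (49% of leukocytes) and CD20 (12%) follow the reported
IIC-subset proportions, checkpoint prevalences are mid-range defaults.
"""

from __future__ import annotations

import warnings
from itertools import combinations as iter_combinations

import pandas as pd

from tilquant.errors import EmptyROIError
from tilquant.syndata import Cohort, CohortSpec, ImageSpec, combination_key, generate_core_image

#: Marker -> prevalence among CD45+ leukocytes.
DEFAULT_ICP_PANEL: dict[str, float] = {
    "CD45": 1.0,
    "CD3": 0.49,
    "CD20": 0.12,
    "TIM-3": 0.30,
    "LAG-3": 0.25,
    "BTLA": 0.25,
    "PD-1": 0.25,
    "PD-L1": 0.20,
    "TIGIT": 0.20,
    "CTLA-4": 0.15,
    "CD26": 0.30,
    "CD39": 0.25,
}

#: The combination whose prognostic effect the planted scenarios carry.
PLANTED_TRIPLE: tuple[str, str, str] = ("CD26", "CD39", "TIM-3")


def icp_image_spec(**overrides) -> ImageSpec:
    """Full-size core spec with the default ICP panel."""
    kw = {"marker_prevalence": dict(DEFAULT_ICP_PANEL)}
    kw.update(overrides)
    return ImageSpec(**kw)


def triple_interaction_scenario(
    n_patients: int = 400, hr: float = 0.5
) -> tuple[ImageSpec, CohortSpec, tuple[str, str, str]]:
    """Planted pure three-way interaction.

    Latent-positive patients differ from negative ones only in the
    all-three-positive cell fraction (p111 = 0.10 vs 0.01 among leukocytes);
    marginals and pairwise joints are identical, so the exact triple is the
    only informative readout in a duplex/triplex scan.
    """
    ispec = icp_image_spec()
    cspec = CohortSpec(n_patients=n_patients, planted_effects={PLANTED_TRIPLE: hr})
    return ispec, cspec, PLANTED_TRIPLE


def coexpression_block_scenario(
    n_patients: int = 400, hr: float = 0.5
) -> tuple[ImageSpec, CohortSpec, tuple[str, str, str], list[tuple[str, ...]], list[str]]:
    """Planted correlated coexpression block.

    Latent-positive patients double the marginal prevalence of the block
    markers and raise their scalar joint fraction (0.25 vs 0.02), so the
    block is visible to single markers, pairwise/triple colocalization and
    PCA alike. Returns (image spec, cohort spec, block, the co-label
    combinations to simulate, the matrix columns the block spans).
    """
    ispec = icp_image_spec()
    cspec = CohortSpec(
        n_patients=n_patients,
        planted_effects={PLANTED_TRIPLE: hr},
        marginal_boost=2.0,
        combo_pair_joint=None,
        combo_joint_hi=0.25,
        combo_joint_lo=0.02,
    )
    combos = [c for c in iter_combinations(sorted(PLANTED_TRIPLE), 2)] + [PLANTED_TRIPLE]
    block_cols = list(PLANTED_TRIPLE) + [combination_key(c) for c in combos]
    return ispec, cspec, PLANTED_TRIPLE, combos, block_cols


def null_scenario(n_patients: int = 73) -> tuple[ImageSpec, CohortSpec]:
    """No planted effects: every marker and combination is prognostically null."""
    return icp_image_spec(), CohortSpec(n_patients=n_patients)


def flagship_image_scenario() -> tuple[ImageSpec, CohortSpec, tuple[str, str, str], list[str]]:
    """End-to-end image-based scenario at desk scale.

    Cores are scaled to 0.2 mm (cell count scaled with core area) so that a
    whole cohort can be rendered and re-quantified from pixels in minutes; a
    CD3-anchored triple carries a strong planted effect (HR 0.3, pure
    three-way interaction) against four decoy checkpoints.
    """
    panel = {"CD3": 0.49, "TIM-3": 0.30, "CD39": 0.25, "CD26": 0.30,
             "LAG-3": 0.25, "BTLA": 0.25}
    ispec = ImageSpec(
        core_diameter_um=200.0,
        cells_per_core_mean=82.0,
        cells_per_core_sd=18.0,
        marker_prevalence=panel,
    )
    planted = ("CD3", "CD39", "TIM-3")
    cspec = CohortSpec(
        n_patients=100,
        cores_per_patient=(3, 3),
        planted_effects={planted: 0.3},
    )
    candidates = ["TIM-3", "CD39", "CD26", "LAG-3", "BTLA"]
    return ispec, cspec, planted, candidates


def simulate_and_quantify(cohort: Cohort, panel_config, seed: int = 0) -> pd.DataFrame:
    """Render and quantify a cohort's cores one at a time (streaming).

    Each core image is generated from the patient's marker profile,
    quantified with ``panel_config``, and discarded before the next one is
    rendered, keeping memory flat across arbitrarily large cohorts. Cores
    with an empty ROI are excluded with a warning, as in batch mode.
    """
    from tilquant.quantify import quantify_core

    frames = []
    for i, (core_id, pid) in enumerate(cohort.core_map.itertuples(index=False)):
        image, _, _ = generate_core_image(
            cohort.image_spec, cohort.profiles[pid], seed=seed * 1_000_003 + i, core_id=core_id
        )
        try:
            frames.append(quantify_core(image, panel_config))
        except EmptyROIError as exc:
            warnings.warn(f"excluding core {core_id!r}: {exc}")
    return pd.concat(frames, ignore_index=True)
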