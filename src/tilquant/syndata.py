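"""Synthetic tissue-microarray data with known ground truth.

Two generators live here:

* an *image* generator producing multichannel core images (one channel per
  marker plus DAPI) together with the ground-truth cell table that produced
  them — the oracle for the quantification stage; and
* a *cohort* generator producing patients with exponential (optionally
  Weibull) survival times whose hazard is multiplied by a planted hazard
  ratio when the patient's latent marker-combination status is positive.

A patient's latent combination status drives both the hazard and the
joint marker prevalence used when simulating that patient's cores, so
imaging noise attenuates but does not destroy a planted effect.

All randomness flows through a single :class:`numpy.random.Generator` per
call; the seed fully determines every output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

from tilquant.errors import ConfigError, SizingError

# Marker prevalences among CD45+ leukocytes used when no panel is supplied.
# CD3 and CD20 fractions follow the reported IIC-subset proportions of an
# immune-enriched NSCLC cohort (49% and 12% of leukocytes); checkpoint
# prevalences are plausible mid-range defaults.
DEFAULT_MARKER_PREVALENCE: dict[str, float] = {
    "CD45": 1.0,
    "CD3": 0.49,
    "CD20": 0.12,
    "TIM-3": 0.30,
    "LAG-3": 0.25,
    "BTLA": 0.25,
}

DAPI = "DAPI"


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def combination_key(markers: Sequence[str]) -> str:
    """Canonical column name for a marker combination: sorted, '+'-joined."""
    return "+".join(sorted(markers))


@dataclass
class ImageSpec:
    """Geometry, content and noise model of one synthetic TMA core image.

    Lengths are in micrometres; intensities in arbitrary units. Defaults
    emulate a 0.6 mm core scanned at 0.3225 um/px carrying 742 +/- 163 cells
    of which 40 +/- 25% are CD45+ leukocytes.
    """

    core_diameter_um: float = 600.0
    um_per_px: float = 0.3225
    cells_per_core_mean: float = 742.0
    cells_per_core_sd: float = 163.0
    leukocyte_fraction_mean: float = 0.40
    leukocyte_fraction_sd: float = 0.25
    cell_radius_range_um: tuple[float, float] = (3.0, 6.0)
    marker_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_PREVALENCE)
    )
    coexpression: Mapping[tuple[str, ...], float] = field(default_factory=dict)
    intensity_fg: tuple[float, float] = (180.0, 20.0)
    intensity_bg: tuple[float, float] = (20.0, 5.0)
    bleedthrough: float = 0.02
    hole_count_range: tuple[int, int] = (0, 3)
    hole_radius_range_um: tuple[float, float] = (10.0, 40.0)
    min_spacing_margin_um: float = 1.5
    gauss_sigma_px: float = 1.0
    canvas_margin_um: float = 15.0
    canvas_px: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def markers(self) -> list[str]:
        return list(self.marker_prevalence)

    @property
    def channels(self) -> list[str]:
        return [DAPI] + self.markers

    def canvas_size(self) -> int:
        needed = int(
            math.ceil((self.core_diameter_um + 2 * self.canvas_margin_um) / self.um_per_px)
        )
        if self.canvas_px is None:
            return needed
        if self.canvas_px < self.core_diameter_um / self.um_per_px:
            raise SizingError(
                f"canvas of {self.canvas_px} px cannot contain a "
                f"{self.core_diameter_um} um core at {self.um_per_px} um/px"
            )
        return self.canvas_px

    def validate(self) -> None:
        for m, p in self.marker_prevalence.items():
            if not 0.0 <= float(p) <= 1.0:
                raise ConfigError(f"prevalence of {m!r} out of [0, 1]: {p}")
        for combo, j in self.coexpression.items():
            for m in combo:
                if m not in self.marker_prevalence:
                    raise ConfigError(f"coexpression references unknown marker {m!r}")
                if not isinstance(j, Mapping) and j > self.marker_prevalence[m] + 1e-12:
                    raise ConfigError(
                        f"joint fraction {j} of {combo} exceeds marginal of {m!r}"
                    )
            if not isinstance(j, Mapping) and not 0.0 <= float(j) <= 1.0:
                raise ConfigError(f"joint fraction of {combo} out of [0, 1]: {j}")
        if not 0.0 <= self.leukocyte_fraction_mean <= 1.0:
            raise ConfigError("leukocyte_fraction_mean out of [0, 1]")
        lo, hi = self.cell_radius_range_um
        if lo <= 0 or hi < lo:
            raise ConfigError("cell_radius_range_um must be positive and ordered")
        self.canvas_size()  # raises SizingError if an explicit canvas is too small


@dataclass
class CohortSpec:
    """Survival model and cohort shape for the synthetic patient generator.

    ``planted_effects`` maps a marker combination (tuple of marker names) to a
    hazard ratio applied multiplicatively when the patient's latent status for
    that combination is positive. Latent-positive patients also receive an
    elevated joint prevalence of the combination markers in their cores
    (``combo_joint_hi`` vs ``combo_joint_lo``).

    For planted *triples*, ``combo_pair_joint`` (when set, the default)
    switches to a fully specified three-way table in which marginals and all
    pairwise joints are identical between latent-positive and -negative
    patients and only the all-positive fraction changes — a pure three-way
    interaction, so the exact combination is the only informative readout.
    Setting ``marginal_boost > 1`` additionally raises the member marginals
    of latent-positive patients, turning the planted effect into a
    correlated coexpression *block* that single markers and PCA can see.
    """

    n_patients: int = 73
    cores_per_patient: tuple[int, int] = (3, 5)
    baseline_hazard: float = 0.0173  # events/month; median OS ~ 40 months
    weibull_shape: float = 1.0
    planted_effects: Mapping[tuple[str, ...], float] = field(default_factory=dict)
    planted_prevalence: float = 0.5
    combo_joint_hi: float = 0.10
    combo_joint_lo: float = 0.01
    combo_pair_joint: float | None = 0.12
    marginal_boost: float = 1.0
    censoring_horizon_months: float = 120.0
    censoring_rate: float = 0.005  # independent exponential censoring, /month

    def validate(self, ispec: ImageSpec) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.cores_per_patient[0] < 1 or self.cores_per_patient[1] < self.cores_per_patient[0]:
            raise ConfigError("cores_per_patient must be an ordered range >= 1")
        if self.censoring_horizon_months <= 0:
            raise ConfigError("censoring horizon must be > 0")
        if self.baseline_hazard <= 0 or self.weibull_shape <= 0:
            raise ConfigError("baseline hazard and Weibull shape must be > 0")
        seen: set[str] = set()
        for combo, hr in self.planted_effects.items():
            if hr <= 0:
                raise ConfigError(f"hazard ratio for {combo} must be > 0")
            for m in combo:
                if m not in ispec.marker_prevalence:
                    raise ConfigError(f"planted combination references unknown marker {m!r}")
                if m in seen:
                    raise ConfigError(f"marker {m!r} appears in more than one planted combination")
                seen.add(m)


@dataclass
class CoreImage:
    """Multichannel pixel data for one core, channel name -> 2-D float array."""

    core_id: str
    channels: dict[str, np.ndarray]
    um_per_px: float

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise ConfigError(f"channel {name!r} not in panel {list(self.channels)}")
        return self.channels[name]


@dataclass
class Cohort:
    """Synthetic cohort bundle: clinical table, core map, per-patient marker
    profiles and the planted ground truth."""

    clinical: pd.DataFrame  # patient_id, months, event, covariates
    core_map: pd.DataFrame  # core_id, patient_id
    profiles: dict[str, dict]  # patient_id -> {"prevalence": ..., "joint": ...}
    truth: pd.DataFrame  # patient_id x planted combination status (bool)
    effects: dict[tuple[str, ...], float]
    image_spec: ImageSpec
    spec: CohortSpec


# ---------------------------------------------------------------------------
# cell-level sampling
# ---------------------------------------------------------------------------

def _positivity_array(
    n_cells: int,
    is_leukocyte: np.ndarray,
    prevalence: Mapping[str, float],
    joint: Mapping[tuple[str, ...], float] | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean positivity matrix (cells x markers, column order = prevalence
    insertion order) under the joint model; see :func:`sample_positivity`."""
    joint = dict(joint or {})
    markers = list(prevalence)
    out = np.zeros((n_cells, len(markers)), dtype=bool)
    col = {m: i for i, m in enumerate(markers)}
    leuk = np.asarray(is_leukocyte, dtype=bool)

    in_combo: set[str] = set()
    for combo in joint:
        for m in combo:
            if m in in_combo:
                raise ConfigError(f"marker {m!r} in more than one joint combination")
            in_combo.add(m)

    for combo, j in joint.items():
        if isinstance(j, Mapping):
            _sample_three_way(out, combo, j, prevalence, leuk, col, rng)
            continue
        j = float(min(j, min(prevalence[m] for m in combo)))
        all_pos = leuk & (rng.random(n_cells) < j)
        for m in combo:
            p = prevalence[m]
            resid = 0.0 if j >= 1.0 else max(0.0, (p - j) / (1.0 - j))
            indep = leuk & ~all_pos & (rng.random(n_cells) < resid)
            out[:, col[m]] = all_pos | indep
    for m in markers:
        if m not in in_combo:
            out[:, col[m]] = leuk & (rng.random(n_cells) < prevalence[m])
    return out


# bit patterns of the 2^3 joint table, ordered (A,B,C)
_TRIPLE_PATTERNS = np.array(
    [[1, 1, 1], [1, 1, 0], [1, 0, 1], [0, 1, 1],
     [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=bool
)


def _sample_three_way(out, combo, spec, prevalence, leuk, col, rng) -> None:
    """Sample a marker triple from a fully specified 2^3 joint table.

    ``spec`` is ``{"p111": t, "pair": q}``: all three pairwise joints equal q
    and the all-positive cell equals t, with marginals from ``prevalence``.
    Fixing q across patients while varying t plants a pure three-way
    interaction: neither single markers nor pairs carry any signal.
    """
    if len(combo) != 3:
        raise ConfigError("table-specified coexpression requires exactly 3 markers")
    p1, p2, p3 = (float(prevalence[m]) for m in combo)
    q = float(spec["pair"])
    t = float(spec["p111"])
    probs = np.array(
        [t, q - t, q - t, q - t,
         p1 - 2 * q + t, p2 - 2 * q + t, p3 - 2 * q + t,
         1.0 - (p1 + p2 + p3) + 3 * q - t]
    )
    if (probs < -1e-12).any():
        raise ConfigError(
            f"infeasible three-way table for {combo}: p111={t}, pair={q}, "
            f"marginals=({p1}, {p2}, {p3})"
        )
    probs = np.clip(probs, 0.0, None)
    probs = probs / probs.sum()
    idx = np.searchsorted(np.cumsum(probs), rng.random(out.shape[0]), side="right")
    idx = np.minimum(idx, 7)
    vals = _TRIPLE_PATTERNS[idx] & leuk[:, None]
    for k, m in enumerate(combo):
        out[:, col[m]] = vals[:, k]


def sample_positivity(
    n_cells: int,
    is_leukocyte: np.ndarray,
    prevalence: Mapping[str, float],
    joint: Mapping[tuple[str, ...], float] | None,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Boolean positivity matrix (cells x markers) under a joint model.

    Markers are expressed on leukocytes only. For each combination in
    ``joint`` with joint fraction j, a cell is all-member-positive with
    probability j; otherwise each member is positive independently with the
    residual probability (p - j)/(1 - j), preserving the marginals.
    Combinations must not share markers.
    """
    markers = list(prevalence)
    return pd.DataFrame(
        _positivity_array(n_cells, is_leukocyte, prevalence, joint, rng), columns=markers
    )


def _tissue_mask(spec: ImageSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Disk-shaped tissue mask with punched holes.

    Returns (mask_with_holes, solid_disk_mask)."""
    n = spec.canvas_size()
    r_px = spec.core_diameter_um / 2.0 / spec.um_per_px
    c = (n - 1) / 2.0
    yy, xx = np.ogrid[:n, :n]
    solid = (yy - c) ** 2 + (xx - c) ** 2 <= r_px**2
    mask = solid.copy()
    k = int(rng.integers(spec.hole_count_range[0], spec.hole_count_range[1] + 1))
    for _ in range(k):
        hr = rng.uniform(*spec.hole_radius_range_um) / spec.um_per_px
        ang = rng.uniform(0, 2 * math.pi)
        rad = rng.uniform(0, max(r_px - hr, 0))
        hy, hx = c + rad * math.sin(ang), c + rad * math.cos(ang)
        rr, cc = draw_disk((hy, hx), hr, shape=(n, n))
        mask[rr, cc] = False
    return mask, solid


def _place_cells(
    n_cells: int,
    radii_px: np.ndarray,
    mask: np.ndarray,
    margin_px: float,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Dart-throwing placement with pairwise spacing >= r_i + r_j + margin.

    Non-overlapping rendered disks keep noiseless connected-component counts
    equal to the planted cell count. Cells that cannot be placed within
    ``max_tries`` are dropped; returns (centroids (k,2) as (row, col), kept
    indices)."""
    n = mask.shape[0]
    inside_r, inside_c = np.nonzero(mask)
    if inside_r.size == 0:
        return np.empty((0, 2)), np.array([], dtype=int)
    pts: list[tuple[float, float]] = []
    rads: list[float] = []
    kept: list[int] = []
    for i in range(n_cells):
        ri = float(radii_px[i])
        for _ in range(max_tries):
            j = int(rng.integers(inside_r.size))
            y = inside_r[j] + rng.uniform(-0.5, 0.5)
            x = inside_c[j] + rng.uniform(-0.5, 0.5)
            if not (0 <= y < n and 0 <= x < n) or not mask[int(round(y)), int(round(x))]:
                continue
            if pts:
                arr = np.asarray(pts)
                d2 = (arr[:, 0] - y) ** 2 + (arr[:, 1] - x) ** 2
                lim = (np.asarray(rads) + ri + margin_px) ** 2
                if np.any(d2 < lim):
                    continue
            pts.append((y, x))
            rads.append(ri)
            kept.append(i)
            break
    return np.asarray(pts).reshape(-1, 2), np.asarray(kept, dtype=int)


def generate_core_cells(
    spec: ImageSpec,
    profile: dict | None = None,
    seed=None,
    core_id: str = "core",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Ground-truth cell table for one core plus its tissue mask.

    ``profile`` optionally overrides ``{"prevalence": ..., "joint": ...}``;
    by default the spec's panel prevalences and coexpression map are used.
    """
    rng = _as_rng(seed)
    prevalence = dict(spec.marker_prevalence)
    joint = {tuple(k): v for k, v in spec.coexpression.items()}
    if profile:
        prevalence.update(profile.get("prevalence", {}))
        joint.update({tuple(k): v for k, v in profile.get("joint", {}).items()})

    mask, _solid = _tissue_mask(spec, rng)
    n_cells = max(0, int(round(rng.normal(spec.cells_per_core_mean, spec.cells_per_core_sd))))
    leuk_frac = float(np.clip(rng.normal(spec.leukocyte_fraction_mean, spec.leukocyte_fraction_sd), 0.0, 1.0))
    is_leuk = rng.random(n_cells) < leuk_frac
    radii_um = rng.uniform(*spec.cell_radius_range_um, size=n_cells)
    radii_px = radii_um / spec.um_per_px

    margin_px = spec.min_spacing_margin_um / spec.um_per_px
    pts, kept = _place_cells(n_cells, radii_px, mask, margin_px, rng)
    is_leuk = is_leuk[kept]
    radii_px = radii_px[kept]

    pos = sample_positivity(len(kept), is_leuk, prevalence, joint, rng)
    cells = pd.DataFrame(
        {
            "cell_id": [f"{core_id}:{i}" for i in range(len(kept))],
            "core_id": core_id,
            "row": pts[:, 0] if len(kept) else np.array([]),
            "col": pts[:, 1] if len(kept) else np.array([]),
            "radius_px": radii_px,
            "cell_class": np.where(is_leuk, "leukocyte", "tumor"),
        }
    )
    cells = pd.concat([cells, pos.add_prefix("pos_")], axis=1)
    return cells, mask


def render_core(
    spec: ImageSpec,
    cells: pd.DataFrame,
    tissue_mask: np.ndarray,
    seed=None,
    core_id: str = "core",
) -> CoreImage:
    """Render a ground-truth cell table into a multichannel image.

    Every positive cell is painted as a Gaussian-smoothed disk in each of its
    channels (all cells in DAPI); tissue autofluorescence background and
    channel bleed-through are then added per spec.
    """
    rng = _as_rng(seed)
    n = spec.canvas_size()
    fg_mean, fg_sd = spec.intensity_fg
    bg_mean, bg_sd = spec.intensity_bg

    signal = {ch: np.zeros((n, n), dtype=np.float64) for ch in spec.channels}
    for _, cell in cells.iterrows():
        rr, cc = draw_disk((cell["row"], cell["col"]), cell["radius_px"], shape=(n, n))
        chans = [DAPI] + [m for m in spec.markers if cell[f"pos_{m}"]]
        for ch in chans:
            inten = max(1.0, rng.normal(fg_mean, fg_sd))
            np.maximum.at(signal[ch], (rr, cc), inten)
    if spec.gauss_sigma_px > 0:
        for ch in signal:
            signal[ch] = ndi.gaussian_filter(signal[ch], spec.gauss_sigma_px)

    out: dict[str, np.ndarray] = {}
    marker_signal = {m: signal[m] for m in spec.markers}
    for ch in spec.channels:
        img = signal[ch].copy()
        if spec.bleedthrough and ch != DAPI:
            for other, s in marker_signal.items():
                if other != ch:
                    img += spec.bleedthrough * s
        if bg_mean > 0 or bg_sd > 0:
            bg = np.clip(rng.normal(bg_mean, bg_sd, size=(n, n)), 0, None)
            img += np.where(tissue_mask, bg, 0.0)
        out[ch] = img.astype(np.float32)
    return CoreImage(core_id=core_id, channels=out, um_per_px=spec.um_per_px)


def generate_core_image(
    spec: ImageSpec,
    profile: dict | None = None,
    seed=None,
    core_id: str = "core",
) -> tuple[CoreImage, pd.DataFrame, np.ndarray]:
    """Convenience wrapper: cell table + rendered image + tissue mask."""
    rng = _as_rng(seed)
    cells, mask = generate_core_cells(spec, profile, rng, core_id)
    image = render_core(spec, cells, mask, rng, core_id)
    return image, cells, mask


# ---------------------------------------------------------------------------
# cohort-level generation
# ---------------------------------------------------------------------------

def generate_cohort(cspec: CohortSpec, ispec: ImageSpec | None = None, seed=None) -> Cohort:
    """Patients with planted marker-combination hazards.

    Survival times are exponential by default (Weibull when
    ``weibull_shape != 1``) with hazard ``baseline * prod(HR_c)`` over the
    patient's latent-positive combinations; censoring is the minimum of an
    administrative horizon and an independent exponential censoring time.
    """
    ispec = ispec or ImageSpec()
    cspec.validate(ispec)
    rng = _as_rng(seed)
    n = cspec.n_patients
    pids = [f"P{i:04d}" for i in range(n)]

    combos = {tuple(k): v for k, v in cspec.planted_effects.items()}
    status = {c: rng.random(n) < cspec.planted_prevalence for c in combos}
    log_hr = np.zeros(n)
    for c, hr in combos.items():
        log_hr += np.where(status[c], math.log(hr), 0.0)
    hazard = cspec.baseline_hazard * np.exp(log_hr)

    k = cspec.weibull_shape
    e = rng.exponential(size=n)
    t_event = (e / hazard) ** (1.0 / k)
    if cspec.censoring_rate > 0:
        c_indep = rng.exponential(1.0 / cspec.censoring_rate, size=n)
    else:
        c_indep = np.full(n, np.inf)
    t_cens = np.minimum(cspec.censoring_horizon_months, c_indep)
    months = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    t_stage = rng.choice(["T1", "T2", "T3", "T4"], size=n, p=[0.15, 0.45, 0.25, 0.15])
    clinical = pd.DataFrame(
        {
            "patient_id": pids,
            "months": months,
            "event": event,
            "T_stage": t_stage,
            "subtype": rng.choice(["ADC", "SQC"], size=n, p=[0.6, 0.4]),
            "sex": rng.choice(["F", "M"], size=n),
            "smoking": rng.choice([0, 1], size=n, p=[0.3, 0.7]),
        }
    )

    rows = []
    profiles: dict[str, dict] = {}
    for i, pid in enumerate(pids):
        ncores = int(rng.integers(cspec.cores_per_patient[0], cspec.cores_per_patient[1] + 1))
        for j in range(ncores):
            rows.append({"core_id": f"{pid}-c{j}", "patient_id": pid})
        prev = dict(ispec.marker_prevalence)
        joint: dict[tuple[str, ...], float] = {tuple(c): v for c, v in ispec.coexpression.items()}
        for c in combos:
            if status[c][i]:
                for m in c:
                    prev[m] = min(0.95, prev[m] * cspec.marginal_boost)
                j_val = cspec.combo_joint_hi
            else:
                j_val = cspec.combo_joint_lo
            if len(c) == 3 and cspec.combo_pair_joint is not None:
                joint[tuple(sorted(c))] = {"p111": j_val, "pair": cspec.combo_pair_joint}
            else:
                joint[tuple(sorted(c))] = min(j_val, min(prev[m] for m in c))
        profiles[pid] = {"prevalence": prev, "joint": joint}

    truth = pd.DataFrame(
        {combination_key(c): status[c] for c in combos}, index=pd.Index(pids, name="patient_id")
    )
    return Cohort(
        clinical=clinical,
        core_map=pd.DataFrame(rows),
        profiles=profiles,
        truth=truth,
        effects={tuple(sorted(c)): v for c, v in combos.items()},
        image_spec=ispec,
        spec=cspec,
    )


def generate_marker_matrix(
    cohort: Cohort,
    combinations: Sequence[Sequence[str]] = (),
    seed=None,
) -> pd.DataFrame:
    """Simulate per-core quantification output without rendering pixels.

    For every core, cell counts, leukocyte fractions and per-cell marker
    positivity are drawn exactly as the image generator would; single-marker
    and requested combination counts are then normalised by the nominal core
    area and log10(x+1)-transformed. The result is a tidy frame with columns
    ``core_id, patient_id, combination_key, raw_count, area_mm2, density,
    log_value`` — the same contract the image-quantification stage writes —
    and is the scalable route for cohort-level simulations.
    """
    wide = simulate_core_matrix(cohort, combinations, seed)
    tidy = wide.reset_index().melt(
        id_vars=["core_id", "patient_id"], var_name="combination_key", value_name="raw_count"
    )
    area_mm2 = math.pi * (cohort.image_spec.core_diameter_um / 2000.0) ** 2
    tidy["raw_count"] = tidy["raw_count"].astype(int)
    tidy["area_mm2"] = area_mm2
    tidy["density"] = tidy["raw_count"] / area_mm2
    tidy["log_value"] = np.log10(tidy["density"] + 1.0)
    return tidy[
        ["core_id", "patient_id", "combination_key", "raw_count", "area_mm2", "density", "log_value"]
    ]


def simulate_core_matrix(
    cohort: Cohort,
    combinations: Sequence[Sequence[str]] = (),
    seed=None,
) -> pd.DataFrame:
    """Per-core raw-count matrix (cores x marker/combination columns).

    Vectorised counting path behind :func:`generate_marker_matrix`: all
    cells of the cohort are sampled in one pass, combination membership is
    evaluated on a per-cell bitmask, and per-core counts come from a single
    bincount per combination. Index is ``core_id`` with a ``patient_id``
    column first.
    """
    rng = _as_rng(seed)
    spec = cohort.image_spec
    markers = spec.markers
    if len(markers) > 62:
        raise ConfigError("bitmask counting supports at most 62 markers")
    combos = [tuple(sorted(c)) for c in combinations]
    for c in combos:
        for m in c:
            if m not in markers:
                raise ConfigError(f"combination references unknown marker {m!r}")
    col_idx = {m: i for i, m in enumerate(markers)}

    core_ids = cohort.core_map["core_id"].tolist()
    pids = cohort.core_map["patient_id"].tolist()
    n_cores = len(core_ids)
    pos_blocks: list[np.ndarray] = []
    core_of_cell: list[np.ndarray] = []
    for i, pid in enumerate(pids):
        prof = cohort.profiles[pid]
        n_cells = max(0, int(round(rng.normal(spec.cells_per_core_mean, spec.cells_per_core_sd))))
        leuk_frac = float(
            np.clip(rng.normal(spec.leukocyte_fraction_mean, spec.leukocyte_fraction_sd), 0.0, 1.0)
        )
        is_leuk = rng.random(n_cells) < leuk_frac
        pos_blocks.append(
            _positivity_array(n_cells, is_leuk, prof["prevalence"], prof["joint"], rng)
        )
        core_of_cell.append(np.full(n_cells, i, dtype=np.int64))
    pos = np.concatenate(pos_blocks) if pos_blocks else np.zeros((0, len(markers)), bool)
    cell_core = np.concatenate(core_of_cell) if core_of_cell else np.zeros(0, np.int64)

    counts = np.zeros((n_cores, len(markers) + len(combos)), dtype=np.int64)
    for j in range(len(markers)):
        counts[:, j] = np.bincount(cell_core[pos[:, j]], minlength=n_cores)
    if combos:
        bits = pos @ (1 << np.arange(len(markers), dtype=np.int64))
        for k, c in enumerate(combos):
            cm = int(sum(1 << col_idx[m] for m in c))
            hit = (bits & cm) == cm
            counts[:, len(markers) + k] = np.bincount(cell_core[hit], minlength=n_cores)

    keys = markers + [combination_key(c) for c in combos]
    out = pd.DataFrame(counts, columns=keys, index=pd.Index(core_ids, name="core_id"))
    out.insert(0, "patient_id", pids)
    return out


def simulate_patient_matrix(
    cohort: Cohort,
    combinations: Sequence[Sequence[str]] = (),
    seed=None,
) -> pd.DataFrame:
    """Patient-level log-density matrix: per-core log10(density + 1) values
    averaged over each patient's replicate cores (the "average" aggregation
    route, computed directly for cohort-scale simulations)."""
    wide = simulate_core_matrix(cohort, combinations, seed)
    area_mm2 = math.pi * (cohort.image_spec.core_diameter_um / 2000.0) ** 2
    logs = np.log10(wide.drop(columns="patient_id") / area_mm2 + 1.0)
    logs["patient_id"] = wide["patient_id"]
    return logs.groupby("patient_id").mean()
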