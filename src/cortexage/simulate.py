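"""Synthetic cortical cohorts with known ground truth.

Real inputs to the pipeline are FreeSurfer-derived morphometric features on
atlas meshes; none are shipped here.  Instead this module simulates cohorts
whose statistical structure matches what the pipeline assumes: smooth spatial
baseline fields per feature (white noise smoothed on the mesh, giving spatial
autocorrelation like real morphometry), a linear per-vertex age trend in a
configurable subset of features, Gaussian measurement noise, and an optional
"accelerated-aging" subgroup whose designated regions behave as if they were a
fixed number of years older.  Each subject also receives a sex, education
years and cognitive scores generated from the true global age gap, so the
group-statistics routines have recoverable effects.

Every draw is a deterministic function of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np

from .atlas import AtlasHierarchy, build_hierarchy
from .model import FEATURE_NAMES, LbaMap, ModelConfig, SurfaceSample, evaluate_mae, predict, train
from .postprocess import apply_bias, fit_bias, remove_medial_wall, smooth, smoothing_matrix
from .stats import Parcellation, geodesic_parcellation, regional_matrix, cohort_difference_tests

__all__ = ["SimulationConfig", "simulate_cohort", "end_to_end_fixture"]


@dataclass
class SimulationConfig:
    """Study-design knobs of the simulator.

    Defaults describe the reference condition used throughout the test suite:
    400 subjects on a (0, 1, 2) two-hemisphere hierarchy, chronological age
    uniform on 45-90 y (echoing an aging-cohort age range), an age signal of
    one z-unit per ~13 y in three of the five features, and feature noise of
    0.5 units.  ``lesion_fraction`` > 0 marks that fraction of subjects as
    "accelerated agers": within ``lesion_regions`` their features reflect an
    age of CA + ``lesion_years``.
    """

    levels: tuple[int, ...] = (0, 1, 2)
    n_subjects: int = 400
    ca_low: float = 45.0
    ca_high: float = 90.0
    #: per-feature slope, feature units per year of age
    slopes: tuple[float, ...] = (-0.04, 0.03, 0.0, -0.04, 0.02)
    #: per-feature Gaussian noise SD, feature units
    noise_sd: tuple[float, ...] = (0.5, 0.5, 0.5, 0.5, 0.5)
    #: smoothing applied to white noise to make baseline fields spatially smooth
    field_smooth_iters: int = 2
    lesion_fraction: float = 0.0
    lesion_regions: tuple[int, ...] = (0,)
    lesion_years: float = 10.0
    sex_offset_years: float = 0.0
    regions_per_hemisphere: int = 8
    cognitive_tests: tuple[str, ...] = ("composite", "TMT_B")
    #: cognitive score per unit of true global age gap (higher = worse)
    cognition_slope: float = 0.5
    cognition_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lesion_fraction <= 1.0:
            raise ValueError("lesion_fraction must lie in [0, 1]")
        if len(self.slopes) != len(FEATURE_NAMES) or len(self.noise_sd) != len(FEATURE_NAMES):
            raise ValueError(f"need {len(FEATURE_NAMES)} slopes and noise SDs")
        if not all(np.isfinite(self.slopes)) or not all(np.isfinite(self.noise_sd)):
            raise ValueError("slopes and noise SDs must be finite")
        if self.ca_high <= self.ca_low or self.ca_low <= 0:
            raise ValueError("require 0 < ca_low < ca_high")


def simulate_cohort(
    config: SimulationConfig,
    hierarchy: AtlasHierarchy | None = None,
    parcellation: Parcellation | None = None,
) -> tuple[list[SurfaceSample], SimpleNamespace]:
    """Draw a cohort of surface samples plus the ground-truth record.

    Feature f at vertex v for subject s is
    ``baseline_f(v) + slope_f * (local_age(v, s) - CA_mid) + noise`` where
    ``local_age`` equals CA everywhere except lesioned regions of lesioned
    subjects (CA + lesion_years) and, for males, plus ``sex_offset_years``.
    Cognitive scores are a linear function of the true global gap plus noise,
    oriented so higher = worse.
    """
    if hierarchy is None:
        hierarchy = build_hierarchy(config.levels)
    mesh = hierarchy.finest
    wall = hierarchy.medial_wall[-1]
    if parcellation is None:
        parcellation = geodesic_parcellation(
            mesh, wall, regions_per_hemisphere=config.regions_per_hemisphere
        )
    rng = np.random.default_rng(config.seed)
    V, F = mesh.n_vertices, len(FEATURE_NAMES)
    ca_mid = 0.5 * (config.ca_low + config.ca_high)

    S = smoothing_matrix(mesh, hops=2)
    baseline = rng.standard_normal((V, F))
    for _ in range(config.field_smooth_iters):
        baseline = S @ baseline

    cas = rng.uniform(config.ca_low, config.ca_high, size=config.n_subjects)
    sexes = rng.integers(0, 2, size=config.n_subjects)
    education = np.clip(rng.normal(14.0, 3.0, size=config.n_subjects), 6.0, 22.0)
    lesioned = rng.random(config.n_subjects) < config.lesion_fraction
    lesion_mask = np.isin(parcellation.labels, config.lesion_regions)

    slopes = np.asarray(config.slopes)
    noise_sd = np.asarray(config.noise_sd)
    samples: list[SurfaceSample] = []
    local_age = np.empty((config.n_subjects, V))
    for i in range(config.n_subjects):
        age_v = np.full(V, cas[i])
        if lesioned[i]:
            age_v[lesion_mask] += config.lesion_years
        if sexes[i] == 1:
            age_v += config.sex_offset_years
        local_age[i] = age_v
        feats = baseline + (age_v[:, None] - ca_mid) * slopes[None, :]
        feats = feats + rng.standard_normal((V, F)) * noise_sd[None, :]
        true_gap = float(np.mean(age_v[~wall] - cas[i]))
        scores = {
            name: config.cognition_slope * true_gap
            + rng.standard_normal() * config.cognition_noise_sd
            for name in config.cognitive_tests
        }
        samples.append(
            SurfaceSample(
                features=feats, ca=float(cas[i]), sex=int(sexes[i]),
                education_years=float(education[i]), cohort="synthetic",
                subject_id=f"sub-{i:04d}", scan_id=f"scan-{i:04d}", scores=scores,
            )
        )
    truth = SimpleNamespace(
        cas=cas, sexes=sexes, education=education, lesioned=lesioned,
        lesion_mask=lesion_mask, local_age=local_age, baseline=baseline,
        gaps=local_age.mean(axis=1) - cas, parcellation=parcellation,
        hierarchy=hierarchy,
    )
    return samples, truth


def end_to_end_fixture(
    config: SimulationConfig,
    model_config: ModelConfig | None = None,
    holdout_fraction: float = 0.2,
) -> SimpleNamespace:
    """Run the whole pipeline on a simulated cohort, returning every stage.

    simulate -> train -> predict -> wall removal -> smooth -> bias-correct ->
    regional statistics.  Mirroring the intended study design, only control
    (non-lesioned) subjects are trained on; the lesioned subgroup is held out
    entirely as a "disease" test cohort, alongside a held-out control test
    cohort.  The bias model is fitted on the control test maps and the same
    coefficients are reused for the lesioned cohort, so lesion-specific
    deviation is preserved.  When a lesioned subgroup exists, regional
    lesioned-minus-control gap differences are tested per region.
    """
    samples, truth = simulate_cohort(config)
    hierarchy = truth.hierarchy
    mesh = hierarchy.finest
    wall = hierarchy.medial_wall[-1]
    if model_config is None:
        model_config = ModelConfig(seed=config.seed)

    controls = np.nonzero(~truth.lesioned)[0]
    lesioned = np.nonzero(truth.lesioned)[0]
    rng = np.random.default_rng(config.seed + 1)
    order = rng.permutation(len(controls))
    n_hold = max(3, int(round(holdout_fraction * len(controls))))
    ctrl_test_idx = controls[order[:n_hold]]
    train_idx = controls[order[n_hold:]]
    test_idx = np.concatenate([ctrl_test_idx, lesioned])
    train_set = [samples[i] for i in train_idx]
    test_set = [samples[i] for i in test_idx]
    test_lesioned = truth.lesioned[test_idx]
    test_cas = np.array([s.ca for s in test_set])

    model, history = train(train_set, model_config, hierarchy)
    raw_maps = predict(test_set, model)
    control_sel = ~test_lesioned
    mae = evaluate_mae(
        [m for m, c in zip(raw_maps, control_sel) if c],
        [s for s, c in zip(test_set, control_sel) if c],
        mask=wall,
    )

    S = smoothing_matrix(mesh, hops=2, keep=np.nonzero(~wall)[0])
    processed: list[LbaMap] = []
    for m in raw_maps:
        m = remove_medial_wall(m, wall)
        processed.append(smooth(m, mesh, S=S))

    control_maps = [m for m, c in zip(processed, control_sel) if c]
    bias = fit_bias(control_maps, test_cas[control_sel], fitted_on="synthetic-control")
    corrected = [apply_bias(m, ca, bias) for m, ca in zip(processed, test_cas)]

    parc = truth.parcellation
    reg_lba, region_ids = regional_matrix(corrected, parc)
    reg_lbag = reg_lba - test_cas[:, None]
    diff_tests = None
    if test_lesioned.any() and control_sel.any():
        diff_tests = cohort_difference_tests(
            reg_lbag[test_lesioned], reg_lbag[control_sel], parc
        )
    return SimpleNamespace(
        samples=samples, truth=truth, hierarchy=hierarchy, model=model,
        history=history, holdout_mae=mae, raw_maps=raw_maps, processed=processed,
        bias=bias, corrected=corrected, regional=reg_lba, regional_gap=reg_lbag,
        region_ids=region_ids, diff_tests=diff_tests, train_idx=train_idx,
        test_idx=test_idx, test_cas=test_cas, test_lesioned=test_lesioned,
        parcellation=parc,
    )
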