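"""Region-level group statistics for local brain-age maps.

Vertex-wise gaps are noisy, so inference runs at the level of a cortical
parcellation: vertex values are averaged within each region, regions are
tested with independent two-tailed t-tests (regional LBA vs the subjects'
chronological ages, or cohort A vs cohort B), and p-values are adjusted with
the Benjamini–Hochberg step-up procedure within each test family.  Sex effects
are assessed with a chronological-age-binned bootstrap (one male and one
female drawn per overlapping integer year of age, 500 replicates).  Relations
to cognition are estimated with ordinary least squares of the brain-age gap
on a standardized cognitive score, controlling for chronological age, sex and
education.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .atlas import Mesh
from .model import LbaMap, SurfaceSample

__all__ = [
    "Parcellation",
    "geodesic_parcellation",
    "regional_means",
    "regional_matrix",
    "region_vs_ca_tests",
    "cohort_difference_tests",
    "sex_bootstrap",
    "cognition_regression",
    "benjamini_hochberg",
]

WALL_LABEL = -1


@dataclass
class Parcellation:
    """Region label per finest-level vertex; ``WALL_LABEL`` marks the wall."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not self.names:
            self.names = {r: f"region_{r:03d}" for r in self.region_ids}

    @property
    def region_ids(self) -> list[int]:
        return sorted(r for r in np.unique(self.labels) if r != WALL_LABEL)

    @classmethod
    def from_text(cls, path) -> "Parcellation":
        """Read a plain label-per-vertex text file (one integer per line)."""
        return cls(labels=np.loadtxt(path, dtype=np.int64))

    @classmethod
    def from_annot(cls, path) -> "Parcellation":
        """Read a FreeSurfer annot file; regions named 'unknown' and
        'medialwall'/'Medial_wall' become the wall label."""
        import nibabel.freesurfer.io as fsio

        labels, _, names = fsio.read_annot(str(path))
        labels = np.asarray(labels, dtype=np.int64)
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in names]
        wall_ids = {i for i, n in enumerate(names)
                    if n.lower() in {"unknown", "medialwall", "medial_wall"}}
        out = labels.copy()
        for w in wall_ids:
            out[labels == w] = WALL_LABEL
        out[labels < 0] = WALL_LABEL
        name_map = {i: n for i, n in enumerate(names) if i not in wall_ids}
        return cls(labels=out, names=name_map)


def geodesic_parcellation(
    mesh: Mesh, wall_mask: np.ndarray, regions_per_hemisphere: int = 74
) -> Parcellation:
    """Deterministic geodesic-patch parcellation of a joint mesh.

    Per hemisphere, seeds are placed by farthest-point sampling (angular
    distance, starting from the lowest-index non-wall vertex) and every
    non-wall vertex joins its nearest seed (ties to the lowest seed index).
    The default region count mirrors sulcus/gyrus-level atlas granularity.
    """
    labels = np.full(mesh.n_vertices, WALL_LABEL, dtype=np.int64)
    offset = 0
    for sl in mesh.hemisphere_slices():
        xyz = mesh.vertices[sl].copy()
        xyz -= xyz.mean(axis=0)
        xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
        keep = np.nonzero(~wall_mask[sl])[0]
        k = min(regions_per_hemisphere, len(keep))
        seeds = [keep[0]]
        d = np.arccos(np.clip(xyz[keep] @ xyz[seeds[0]], -1, 1))
        for _ in range(1, k):
            nxt = keep[int(np.argmax(d))]
            seeds.append(nxt)
            d = np.minimum(d, np.arccos(np.clip(xyz[keep] @ xyz[nxt], -1, 1)))
        seed_xyz = xyz[seeds]
        ang = np.arccos(np.clip(xyz[keep] @ seed_xyz.T, -1, 1))
        labels[sl.start + keep] = offset + np.argmin(ang, axis=1)
        offset += k
    return Parcellation(labels=labels)


def regional_means(lba_map: LbaMap, parcellation: Parcellation) -> dict[int, float]:
    """Unweighted mean of vertex values per region, wall excluded.

    Accepts full-mesh or wall-removed maps (via their vertex index).  Regions
    with no vertices in the map are dropped with a warning.
    """
    idx = lba_map.vertex_index
    labels = parcellation.labels if idx is None else parcellation.labels[idx]
    out: dict[int, float] = {}
    for r in parcellation.region_ids:
        sel = labels == r
        if not sel.any():
            warnings.warn(f"region {r} has no vertices in this map; dropped")
            continue
        out[r] = float(lba_map.lba[sel].mean())
    return out


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvals, dtype=np.float64)
    ok = ~np.isnan(p)
    adj = np.full_like(p, np.nan)
    if ok.any():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return adj


def _result_frame(parc: Parcellation, means, stat, p) -> pd.DataFrame:
    df = pd.DataFrame({
        "region": parc.region_ids,
        "name": [parc.names[r] for r in parc.region_ids],
        "mean": means,
        "t": stat,
        "p": p,
    })
    df["p_adj"] = benjamini_hochberg(df["p"].to_numpy())
    df["significant"] = df["p_adj"] < 0.05
    return df


def regional_matrix(maps: list[LbaMap], parc: Parcellation) -> tuple[np.ndarray, list[int]]:
    """(S, R) matrix of regional means across scans, plus the region id order."""
    rows = [regional_means(m, parc) for m in maps]
    regions = sorted(set.intersection(*(set(r) for r in rows)))
    return np.array([[row[r] for r in regions] for row in rows]), regions


def region_vs_ca_tests(
    regional_lba: np.ndarray,
    cas: np.ndarray,
    parcellation: Parcellation,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-region independent two-tailed t-test of regional LBAs against CAs.

    ``regional_lba`` is (S, R) with columns ordered as
    ``parcellation.region_ids``.  Regions whose adjusted p >= 0.05 are flagged
    insignificant.  Mean reported is the regional mean gap (LBA - CA).
    """
    regional_lba = np.asarray(regional_lba, dtype=np.float64)
    cas = np.asarray(cas, dtype=np.float64)
    if regional_lba.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    stat, p, means = [], [], []
    for col in regional_lba.T:
        means.append(float((col - cas).mean()))
        if col.var() == 0 and cas.var() == 0:
            t_val, p_val = (np.nan, np.nan) if col.mean() != cas.mean() else (0.0, 1.0)
        else:
            t_val, p_val = sps.ttest_ind(col, cas, equal_var=equal_var)
        stat.append(float(t_val))
        p.append(float(p_val))
    return _result_frame(parcellation, means, stat, p)


def cohort_difference_tests(
    regional_a: np.ndarray,
    regional_b: np.ndarray,
    parcellation: Parcellation,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-region independent t-test of cohort A vs cohort B regional values.

    The reported mean is the A - B difference of regional means (e.g. the
    disease-minus-control map); p-values are BH-adjusted across regions.
    """
    a = np.asarray(regional_a, dtype=np.float64)
    b = np.asarray(regional_b, dtype=np.float64)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both cohorts must be non-empty")
    stat, p, diffs = [], [], []
    for col_a, col_b in zip(a.T, b.T):
        diffs.append(float(col_a.mean() - col_b.mean()))
        if col_a.var() == 0 and col_b.var() == 0:
            t_val, p_val = (np.nan, np.nan) if col_a.mean() != col_b.mean() else (0.0, 1.0)
        else:
            t_val, p_val = sps.ttest_ind(col_a, col_b, equal_var=equal_var)
        stat.append(float(t_val))
        p.append(float(p_val))
    return _result_frame(parcellation, diffs, stat, p)


def sex_bootstrap(
    cohort: list[SurfaceSample],
    gbags: np.ndarray,
    reps: int = 500,
    seed: int = 0,
    regional: np.ndarray | None = None,
) -> dict:
    """CA-binned bootstrap of male-minus-female brain-age-gap differences.

    For each replicate and each overlapping integer year of chronological age,
    one male and one female are drawn uniformly at random and their gap
    difference recorded; the replicate statistic is the mean difference across
    years.  Returns the replicate distribution, its mean and a percentile 95%
    interval, globally and (optionally) per region.
    """
    sexes = np.array([s.sex for s in cohort])
    years = np.array([int(np.floor(s.ca)) for s in cohort])
    gbags = np.asarray(gbags, dtype=np.float64)
    male_years = set(years[sexes == 1])
    female_years = set(years[sexes == 0])
    overlap = sorted(male_years & female_years)
    if not overlap:
        raise ValueError("no overlapping integer years of CA between sexes")
    by_year = {
        y: (np.nonzero((years == y) & (sexes == 1))[0],
            np.nonzero((years == y) & (sexes == 0))[0])
        for y in overlap
    }
    rng = np.random.default_rng(seed)
    glob = np.empty(reps)
    reg = None if regional is None else np.empty((reps, regional.shape[1]))
    for r in range(reps):
        g_diffs, r_diffs = [], []
        for y in overlap:
            males, females = by_year[y]
            i = males[rng.integers(len(males))]
            j = females[rng.integers(len(females))]
            g_diffs.append(gbags[i] - gbags[j])
            if regional is not None:
                r_diffs.append(regional[i] - regional[j])
        glob[r] = np.mean(g_diffs)
        if reg is not None:
            reg[r] = np.mean(r_diffs, axis=0)
    out = {
        "global": glob,
        "global_mean": float(glob.mean()),
        "global_ci": (float(np.percentile(glob, 2.5)), float(np.percentile(glob, 97.5))),
    }
    if reg is not None:
        out["regional"] = reg
        out["regional_mean"] = reg.mean(axis=0)
        out["regional_ci"] = np.percentile(reg, [2.5, 97.5], axis=0)
    return out


#: Cognitive tests whose raw scale has higher = better; they are sign-flipped
#: so that in every regression a higher score means worse performance.
HIGHER_IS_BETTER = {"MMSE", "RAVLT_immediate", "RAVLT_learning", "DigitSymbol"}

TMTB_CEILING = 300.0


def cognition_regression(
    cohort: list[SurfaceSample],
    bags: np.ndarray,
    test_name: str,
    higher_is_better: bool | None = None,
) -> dict:
    """OLS of brain-age gap on one standardized cognitive score plus covariates.

    The score is z-standardized over included subjects and oriented so higher
    = worse (tests in ``HIGHER_IS_BETTER`` are sign-flipped); TMT-B scores
    equal to 300 are excluded as ceiling effects.  Covariates: CA, sex,
    education years.  Returns the score-term beta and p plus the transform
    record; BH correction across a battery is applied by the caller via
    :func:`benjamini_hochberg`.
    """
    rows = [
        (bags[i], s.scores[test_name], s.ca, s.sex, s.education_years)
        for i, s in enumerate(cohort)
        if test_name in s.scores and np.isfinite(s.scores[test_name])
    ]
    if test_name.upper().startswith("TMT"):
        rows = [r for r in rows if r[1] != TMTB_CEILING]
    if len(rows) < 5:
        raise ValueError(f"fewer than 5 complete cases for {test_name}")
    bag, score, ca, sex, edu = map(np.asarray, zip(*rows))
    if higher_is_better is None:
        higher_is_better = test_name in HIGHER_IS_BETTER
    flipped = bool(higher_is_better)
    if flipped:
        score = -score
    mu, sd = score.mean(), score.std(ddof=0)
    if sd == 0:
        raise ValueError(f"{test_name}: score is constant after exclusions")
    score_z = (score - mu) / sd

    X = np.column_stack([score_z, ca, sex, edu])
    names = ["score", "ca", "sex", "education"]
    for j, name in enumerate(names):
        if np.std(X[:, j]) == 0:
            raise ValueError(f"design column '{name}' is constant (collinear with intercept)")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(bag, design).fit()
    return {
        "test": test_name,
        "beta": float(fit.params[1]),
        "p": float(fit.pvalues[1]),
        "n": len(rows),
        "transform": {"flipped": flipped, "mean": float(mu), "sd": float(sd)},
    }
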