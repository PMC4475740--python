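"""Synthetic BOLD-like cohorts with the correlation structure of an aging study.

The generator emulates the empirical regularities a resting-state group
analysis assumes: strong correlation between interhemispheric homologous
regions, moderately elevated correlation within a lobe, a weak generic
background, and a set of designated long-distance "affected" edges whose
strength is attenuated in a graded, group-ordered way (controls > mild
impairment > disease).  A per-subject latent strength drives both the
subject's realized affected-edge correlations and their cognitive screening
score (MMSE, integer 0-30), so that edge strength and cognition are
positively coupled in the population.

Temporal model: stationary AR(1) with correlated Gaussian innovations.  With
a shared autoregressive coefficient ``phi`` the lag-0 cross-correlation of the
stationary process equals the target correlation matrix exactly, so the
sample correlation converges to the planted value as T grows.

Randomness: one integer seed feeds a hierarchical `numpy.random.SeedSequence`
scheme with one stream per subject, keyed by (seed, group code, position in
group), so changing one group's size does not reshuffle other subjects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import Atlas, default_atlas
from .preprocess import SubjectTimeSeries

__all__ = [
    "CovarianceSpec",
    "MMSEModel",
    "CohortConfig",
    "GroundTruth",
    "build_group_correlation",
    "nearest_pd",
    "simulate_subject",
    "simulate_mmse",
    "simulate_cohort",
    "render_toy_image",
    "default_spec",
]

logger = logging.getLogger(__name__)

GROUPS = ("NC", "MCI", "AD")
_GROUP_CODE = {g: k for k, g in enumerate(GROUPS)}


@dataclass(frozen=True)
class CovarianceSpec:
    """Target correlation structure for one cohort.

    ``affected_edges`` lists (i, j) pairs whose correlation equals
    ``affected_correlation`` minus the group's entry in
    ``effect_size_by_group``; all other pairs follow the homologue /
    intralobe / background rules (affected overrides the rest).
    ``strength_jitter_sd`` is a per-subject Gaussian perturbation of the
    affected-edge level (in correlation units) that creates within-group
    variation in connectivity strength — the latent quantity MMSE couples to.
    """

    n_regions: int
    base_correlation: float = 0.10
    homologue_correlation: float = 0.60
    intralobe_correlation: float = 0.30
    affected_correlation: float = 0.60
    affected_edges: tuple[tuple[int, int], ...] = ()
    effect_size_by_group: dict[str, float] = field(
        default_factory=lambda: {"NC": 0.0, "MCI": 0.15, "AD": 0.30}
    )
    strength_jitter_sd: float = 0.10

    def __post_init__(self) -> None:
        for name in ("base_correlation", "homologue_correlation", "intralobe_correlation", "affected_correlation"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (-1, 1)")
        edges = tuple((int(i), int(j)) for i, j in self.affected_edges)
        for i, j in edges:
            if not (0 <= i < j < self.n_regions):
                raise ValueError(f"affected edge ({i}, {j}) invalid for {self.n_regions} regions")
        object.__setattr__(self, "affected_edges", edges)
        levels = {g: self.affected_level(g) for g in self.effect_size_by_group}
        for g, lv in levels.items():
            if not -1.0 < lv < 1.0:
                raise ValueError(f"affected-edge correlation for {g} is {lv}, outside (-1, 1)")
        order = [g for g in GROUPS if g in levels]
        for a, b in zip(order, order[1:]):
            if levels[a] < levels[b]:
                raise ValueError(
                    f"effect sizes must give ordered affected-edge correlation "
                    f"(got {a}={levels[a]} < {b}={levels[b]})"
                )

    def affected_level(self, group: str) -> float:
        return self.affected_correlation - self.effect_size_by_group[group]


@dataclass(frozen=True)
class MMSEModel:
    """Linear model for the cognitive screening score.

    score = round(intercept[group] + slope * latent_strength + N(0, noise_sd)),
    clamped to the instrument's 0-30 range.
    """

    intercepts: dict[str, float] = field(
        default_factory=lambda: {"NC": 22.6, "MCI": 22.5, "AD": 17.0}
    )
    slope: float = 10.0
    noise_sd: float = 2.0


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulation parameters.

    Defaults mirror a typical aging-cohort acquisition: 27 controls, 27 mild
    cognitive impairment, 35 disease subjects; 200 timepoints at a 2-second
    sampling interval (a 6 min 40 s run); AR(1) coefficient 0.4.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: {"NC": 27, "MCI": 27, "AD": 35})
    n_timepoints: int = 200
    sampling_interval: float = 2.0
    ar_coefficient: float = 0.4
    mmse_model: MMSEModel = field(default_factory=MMSEModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in _GROUP_CODE:
                raise ValueError(f"unknown group label {g!r}; expected one of {GROUPS}")
            if n <= 0:
                raise ValueError(f"group size for {g} must be positive, got {n}")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in [0, 1)")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure recorded before time-series noise; used by recovery tests.

    ``target_by_group`` holds the realized per-edge correlation targets after
    positive-definite repair (the repair can shrink strongly perturbed
    entries, so these — not the nominal spec levels — are what sample
    correlations converge to); ``nominal_by_group`` keeps the spec levels.
    """

    affected_edges: tuple[tuple[int, int], ...]
    target_by_group: dict[str, tuple[float, ...]]
    nominal_by_group: dict[str, float]
    subject_latent: dict[str, float]
    subject_mmse: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "affected_edges": [list(e) for e in self.affected_edges],
            "target_by_group": {g: list(v) for g, v in self.target_by_group.items()},
            "nominal_by_group": self.nominal_by_group,
            "subject_latent": self.subject_latent,
            "subject_mmse": self.subject_mmse,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            affected_edges=tuple((int(i), int(j)) for i, j in d["affected_edges"]),
            target_by_group={k: tuple(map(float, v)) for k, v in d["target_by_group"].items()},
            nominal_by_group={k: float(v) for k, v in d["nominal_by_group"].items()},
            subject_latent={k: float(v) for k, v in d["subject_latent"].items()},
            subject_mmse={k: int(v) for k, v in d["subject_mmse"].items()},
        )


# Long-distance interlobe pairs attenuated by default: posterior-midline and
# temporal nodes against frontal/parietal targets, both hemispheres.
_DEFAULT_AFFECTED = (
    ("PCC", "left", "SFGmed", "right"),
    ("PCC", "right", "SFGmed", "left"),
    ("PCUN", "left", "SFGmed", "left"),
    ("PCUN", "right", "SFGmed", "right"),
    ("PHG", "left", "MFG", "left"),
    ("PHG", "right", "MFG", "right"),
    ("STG", "left", "IPL", "left"),
    ("STG", "right", "IPL", "right"),
    ("MTG", "left", "SFGdor", "left"),
    ("MTG", "right", "SFGdor", "right"),
    ("ITG", "left", "SPG", "left"),
    ("ITG", "right", "SPG", "right"),
    ("TPOsup", "left", "ANG", "left"),
    ("TPOsup", "right", "ANG", "right"),
    ("HES", "left", "PCUN", "left"),
    ("HES", "right", "PCUN", "right"),
    ("FFG", "left", "MCC", "left"),
    ("FFG", "right", "MCC", "right"),
    ("STG", "left", "SFGmed", "left"),
    ("STG", "right", "SFGmed", "right"),
)


def default_spec(atlas: Atlas | None = None, n_affected: int = 20) -> CovarianceSpec:
    """Default covariance spec: attenuated long-distance (interlobe) edges.

    On the bundled atlas the affected set is a fixed list of 20
    posterior-midline / temporal to frontal / parietal pairs.  On other
    parcellations the first ``n_affected`` interlobe, non-homologous pairs
    (in edge order, skipping shared nodes while possible) are used instead.
    """
    atlas = atlas or default_atlas()
    edges: list[tuple[int, int]] = []
    try:
        for a_abbr, a_hemi, b_abbr, b_hemi in _DEFAULT_AFFECTED:
            i = atlas.find(a_abbr, a_hemi).index
            j = atlas.find(b_abbr, b_hemi).index
            edges.append((min(i, j), max(i, j)))
    except KeyError:
        edges = []
        used: set[int] = set()
        pairs = [(int(i), int(j)) for i, j in atlas.edges()]
        for relax in (False, True):
            for i, j in pairs:
                if len(edges) >= n_affected:
                    break
                a, b = atlas.regions[i], atlas.regions[j]
                if a.lobe == b.lobe or a.abbreviation == b.abbreviation:
                    continue
                if not relax and (i in used or j in used):
                    continue
                if (i, j) not in edges:
                    edges.append((i, j))
                    used.update((i, j))
    return CovarianceSpec(n_regions=atlas.n_regions, affected_edges=tuple(edges))


def build_group_correlation(spec: CovarianceSpec, group: str, atlas: Atlas) -> np.ndarray:
    """Target correlation matrix for one group, before positive-definite repair.

    Rule precedence per pair: affected edge > interhemispheric homologue >
    same lobe > background.
    """
    if atlas.n_regions != spec.n_regions:
        raise ValueError("atlas size does not match spec.n_regions")
    if group not in spec.effect_size_by_group:
        raise ValueError(f"group {group!r} has no effect size in spec")
    n = spec.n_regions
    m = np.full((n, n), spec.base_correlation)
    lobes = np.array([r.lobe for r in atlas.regions])
    same_lobe = lobes[:, None] == lobes[None, :]
    m[same_lobe] = spec.intralobe_correlation
    for i, j in atlas.homologue_pairs():
        m[i, j] = m[j, i] = spec.homologue_correlation
    level = spec.affected_level(group)
    for i, j in spec.affected_edges:
        m[i, j] = m[j, i] = level
    np.fill_diagonal(m, 1.0)
    if np.any(np.abs(m[~np.eye(n, dtype=bool)]) >= 1.0):
        raise ValueError("spec produces off-diagonal |r| >= 1")
    return m


def nearest_pd(matrix: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Repair a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped from below, the diagonal is renormalized to 1,
    and the two steps iterate until the smallest eigenvalue is at least
    ``epsilon``.  An input that is already sufficiently positive definite is
    returned essentially unchanged.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("input matrix is not symmetric")
    m = 0.5 * (m + m.T)
    for _ in range(100):
        w, v = np.linalg.eigh(m)
        if w[0] >= epsilon and np.allclose(np.diag(m), 1.0, atol=1e-12):
            return m
        w_clipped = np.maximum(w, 1.5 * epsilon)
        m = (v * w_clipped) @ v.T
        d = np.sqrt(np.diag(m))
        m = m / np.outer(d, d)
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 1.0)
    raise RuntimeError("positive-definite repair failed to converge")


def simulate_subject(
    correlation: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
) -> SubjectTimeSeries:
    """Draw one subject's T x N series from the stationary AR(1) model.

    ``x_0 ~ N(0, C)`` and ``x_t = phi * x_{t-1} + sqrt(1 - phi^2) * L e_t``
    with ``L L' = C``, so the stationary lag-0 covariance equals the target
    correlation matrix ``C`` for any ``phi`` in [0, 1).
    """
    c = np.asarray(correlation, dtype=float)
    if config.n_timepoints < 10:
        raise ValueError("n_timepoints must be at least 10")
    try:
        chol = np.linalg.cholesky(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc
    phi = config.ar_coefficient
    n_t, n = config.n_timepoints, c.shape[0]
    innov = rng.standard_normal((n_t, n)) @ chol.T
    x = np.empty((n_t, n))
    x[0] = innov[0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, n_t):
        x[t] = phi * x[t - 1] + scale * innov[t]
    return SubjectTimeSeries(x, config.sampling_interval)


def simulate_mmse(
    latent_strength: float,
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
) -> int:
    """Integer MMSE score from the linear cognition model, clamped to [0, 30]."""
    model = config.mmse_model
    raw = model.intercepts[group] + model.slope * latent_strength
    if model.noise_sd > 0:
        raw += rng.normal(0.0, model.noise_sd)
    return int(np.clip(round(raw), 0, 30))


def _subject_rng(seed: int, group: str, k: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _GROUP_CODE[group], k]))


def simulate_cohort(
    spec: CovarianceSpec,
    config: CohortConfig,
    atlas: Atlas | None = None,
) -> tuple[list[SubjectTimeSeries], pd.DataFrame, GroundTruth]:
    """Generate a full cohort: one series per subject, covariates, ground truth.

    Per subject, the group's affected-edge level is perturbed by
    ``N(0, strength_jitter_sd)`` (shared across that subject's affected
    edges), giving a subject-specific target matrix; the perturbed level is
    the latent strength that feeds the MMSE model.
    """
    atlas = atlas or default_atlas()
    if config.n_timepoints < 2 * spec.n_regions:
        logger.warning(
            "n_timepoints=%d < 2 * n_regions=%d; sample correlation estimates will be noisy",
            config.n_timepoints, 2 * spec.n_regions,
        )
    series: list[SubjectTimeSeries] = []
    rows = []
    latents: dict[str, float] = {}
    mmses: dict[str, int] = {}
    group_base = {}
    realized = {}
    for group in (g for g in GROUPS if g in config.group_sizes):
        base = build_group_correlation(spec, group, atlas)
        group_base[group] = base
        repaired = nearest_pd(base)
        realized[group] = tuple(float(repaired[i, j]) for i, j in spec.affected_edges)
    for group, base in group_base.items():
        level = spec.affected_level(group)
        for k in range(config.group_sizes[group]):
            rng = _subject_rng(config.seed, group, k)
            sid = f"{group}{k + 1:03d}"
            jitter = rng.normal(0.0, spec.strength_jitter_sd) if spec.strength_jitter_sd > 0 else 0.0
            subj_level = float(np.clip(level + jitter, -0.95, 0.95))
            target = base.copy()
            for i, j in spec.affected_edges:
                target[i, j] = target[j, i] = subj_level
            target = nearest_pd(target)
            series.append(simulate_subject(target, config, rng))
            mmse = simulate_mmse(subj_level, group, config, rng)
            latents[sid] = subj_level
            mmses[sid] = mmse
            rows.append({"subject_id": sid, "group": group, "mmse": mmse})
    covariates = pd.DataFrame(rows)
    truth = GroundTruth(
        affected_edges=spec.affected_edges,
        target_by_group=realized,
        nominal_by_group={g: spec.affected_level(g) for g in group_base},
        subject_latent=latents,
        subject_mmse=mmses,
    )
    return series, covariates, truth


def render_toy_image(
    ts: SubjectTimeSeries,
    atlas: Atlas,
    voxels_per_region: int = 3,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint regional series into a toy 4D volume plus an integer label volume.

    Region ``k`` occupies ``voxels_per_region`` voxels in a (N, V, 1) grid;
    each voxel carries the region's series plus independent Gaussian noise.
    The pair round-trips through regional extraction: with ``noise_sd=0`` the
    extracted means equal the planted series exactly.
    """
    if voxels_per_region < 1:
        raise ValueError("every region needs at least one voxel")
    if ts.n_regions != atlas.n_regions:
        raise ValueError("series column count does not match atlas")
    rng = rng or np.random.default_rng()
    n, v, n_t = atlas.n_regions, voxels_per_region, ts.n_timepoints
    labels = np.zeros((n, v, 1), dtype=int)
    image = np.zeros((n, v, 1, n_t))
    for region in atlas.regions:
        labels[region.index, :, 0] = region.label_value
        block = np.tile(ts.values[:, region.index], (v, 1))
        if noise_sd > 0:
            block = block + rng.normal(0.0, noise_sd, size=block.shape)
        image[region.index, :, 0, :] = block
    return image, labels
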