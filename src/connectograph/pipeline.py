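"""End-to-end orchestration: simulate or load a cohort, analyze, write artifacts.

Artifacts are plain text: per-subject Fisher-z matrices and regional series as
TSV with atlas abbreviations as headers (17 significant digits, so write/read
round-trips to full double precision), covariates and altered-edge tables as
CSV, summaries and ground truth as JSON, plus a provenance file recording the
configuration, seed, and package version — enough to re-execute an identical
run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import Atlas, default_atlas, load_atlas
from .cognition import correlation_report, edge_mmse_correlation
from .connectome import CohortStack, group_difference_matrix, group_mean_matrix, subject_connectivity
from .edge_stats import group_strength_anova, select_altered_edges, summarize_altered
from .preprocess import NuisanceSet, SubjectTimeSeries, preprocess_subject
from .simulate import CohortConfig, CovarianceSpec, default_spec, simulate_cohort

__all__ = [
    "RunConfig",
    "write_matrix",
    "read_matrix",
    "write_cohort",
    "read_manifest",
    "analyze_cohort",
    "run_full_pipeline",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


def write_matrix(path: str | Path, matrix: np.ndarray, names: list[str]) -> None:
    """Write a square matrix as TSV with region names as header row and column."""
    frame = pd.DataFrame(matrix, index=names, columns=names)
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return frame.to_numpy(dtype=float), list(frame.columns)


def write_timeseries(path: str | Path, ts: SubjectTimeSeries, names: list[str]) -> None:
    pd.DataFrame(ts.values, columns=names).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_timeseries(path: str | Path, sampling_interval: float = 2.0) -> SubjectTimeSeries:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return SubjectTimeSeries(frame.to_numpy(dtype=float), sampling_interval, tuple(frame.columns))


def write_cohort(
    outdir: str | Path,
    series: list[SubjectTimeSeries],
    covariates: pd.DataFrame,
    atlas: Atlas,
    truth=None,
) -> Path:
    """Write one TSV per subject, a covariates CSV, a manifest CSV, and ground truth.

    Returns the manifest path; the manifest links subject files to covariates
    (columns subject_id, group, mmse, timeseries_path).
    """
    outdir = Path(outdir)
    tsdir = outdir / "timeseries"
    tsdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts, (_, cov) in zip(series, covariates.iterrows(), strict=True):
        fname = f"{cov['subject_id']}.tsv"
        write_timeseries(tsdir / fname, ts, atlas.names)
        rows.append(
            {
                "subject_id": cov["subject_id"],
                "group": cov["group"],
                "mmse": cov["mmse"],
                "timeseries_path": str(Path("timeseries") / fname),
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    covariates.to_csv(outdir / "covariates.csv", index=False)
    if truth is not None:
        truth.to_json(outdir / "ground_truth.json")
    return manifest


def read_manifest(
    path: str | Path,
    atlas: Atlas,
    sampling_interval: float = 2.0,
    allowed_groups: tuple[str, ...] = ("NC", "MCI", "AD"),
) -> tuple[list[SubjectTimeSeries], pd.DataFrame]:
    """Load a cohort manifest (subject_id, group, mmse, timeseries_path) and validate.

    Errors on unknown group labels, duplicate subject ids, missing files,
    column counts that do not match the atlas, and subjects with differing T.
    """
    path = Path(path)
    table = pd.read_csv(path)
    required = {"subject_id", "group", "mmse", "timeseries_path"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")
    dup = table["subject_id"][table["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id in manifest: {sorted(set(dup))}")
    unknown = sorted(set(table["group"]) - set(allowed_groups))
    if unknown:
        raise ValueError(f"unknown group labels in manifest: {unknown}")
    series = []
    n_t = None
    for _, row in table.iterrows():
        ts_path = Path(row["timeseries_path"])
        if not ts_path.is_absolute():
            ts_path = path.parent / ts_path
        if not ts_path.exists():
            raise FileNotFoundError(f"subject {row['subject_id']}: missing file {ts_path}")
        ts = read_timeseries(ts_path, sampling_interval)
        if ts.n_regions != atlas.n_regions:
            raise ValueError(
                f"subject {row['subject_id']}: {ts.n_regions} columns, atlas has {atlas.n_regions}"
            )
        if n_t is None:
            n_t = ts.n_timepoints
        elif ts.n_timepoints != n_t:
            raise ValueError(
                f"subject {row['subject_id']}: T={ts.n_timepoints} differs from first subject's T={n_t}"
            )
        series.append(ts)
    covariates = table[["subject_id", "group", "mmse"]].reset_index(drop=True)
    return series, covariates


@dataclass
class RunConfig:
    """Configuration for a full simulate-or-load, preprocess, analyze run."""

    outdir: str = "connectograph_run"
    atlas_path: str | None = None
    manifest_path: str | None = None
    simulate: bool = True
    seed: int = 0
    n_timepoints: int = 200
    sampling_interval: float = 2.0
    low_hz: float = 0.01
    high_hz: float = 0.08
    skip_bandpass: bool = False
    skip_nuisance: bool = True
    control: str = "NC"
    patient: str = "AD"
    alpha_one: float = 0.05
    q_two: float = 0.05
    alpha_mmse: float = 0.05
    equal_var: bool = True
    absolute_strength: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha_one", "q_two", "alpha_mmse"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        nyquist = 0.5 / self.sampling_interval
        if not (0 < self.low_hz < self.high_hz < nyquist):
            raise ValueError(
                f"band edges ({self.low_hz}, {self.high_hz}) invalid for Nyquist {nyquist} Hz"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def build_stack(
    series: list[SubjectTimeSeries],
    covariates: pd.DataFrame,
    atlas: Atlas,
    config: RunConfig | None = None,
    nuisance: list[NuisanceSet | None] | None = None,
) -> CohortStack:
    """Condition every subject's series and assemble the Fisher-z stack."""
    config = config or RunConfig()
    matrices = []
    for k, ts in enumerate(series):
        nui = nuisance[k] if nuisance is not None else None
        conditioned = preprocess_subject(
            ts, nui, low=config.low_hz, high=config.high_hz, skip_bandpass=config.skip_bandpass
        )
        matrices.append(subject_connectivity(conditioned, str(covariates.iloc[k]["subject_id"])))
    return CohortStack.from_matrices(matrices, covariates, atlas)


def analyze_cohort(stack: CohortStack, config: RunConfig | None = None) -> dict:
    """Run the group analysis on a conditioned cohort stack.

    Returns a result bundle: group mean and difference matrices, the ANOVA on
    mean strength, the dual-criterion altered-edge table, its topology
    summary, and the MMSE correlation table and report.
    """
    config = config or RunConfig()
    groups = stack.groups
    mean_abs = {g: group_mean_matrix(stack, g, absolute=True) for g in groups}
    diffs = {}
    for a_idx in range(len(groups)):
        for b_idx in range(a_idx + 1, len(groups)):
            a, b = groups[a_idx], groups[b_idx]
            diffs[f"{a}_minus_{b}"] = group_difference_matrix(stack, a, b)
    anova = group_strength_anova(stack, absolute=config.absolute_strength, equal_var=config.equal_var)
    altered = select_altered_edges(
        stack, config.control, config.patient,
        alpha_one=config.alpha_one, q_two=config.q_two, equal_var=config.equal_var,
    )
    summary = summarize_altered(altered, stack.atlas)
    patient_groups = [g for g in groups if g != config.control]
    group_sets = [[g] for g in patient_groups]
    if len(patient_groups) > 1:
        group_sets.append(patient_groups)
    cognition_tables = [
        edge_mmse_correlation(stack, altered, groups=gset, alpha=config.alpha_mmse)
        for gset in group_sets
    ]
    cognition = (
        pd.concat(cognition_tables, ignore_index=True)
        if cognition_tables
        else pd.DataFrame(columns=["i", "j", "group_set", "r", "p", "n"])
    )
    return {
        "mean_abs": mean_abs,
        "differences": diffs,
        "anova": anova,
        "altered": altered,
        "summary": summary,
        "cognition": cognition,
        "cognition_report": correlation_report(cognition),
    }


def run_full_pipeline(config: RunConfig) -> dict:
    """Simulate (or load) a cohort, analyze it, and write all artifacts to disk.

    Identical config + seed gives byte-identical numeric outputs.  Writes:
    per-subject z matrices, group mean/difference matrices, the altered-edge
    CSV, a summary JSON (including the ANOVA), the cognition CSV + report,
    and a provenance JSON.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    atlas = load_atlas(config.atlas_path) if config.atlas_path else default_atlas()

    if config.simulate:
        spec = default_spec(atlas)
        cohort_cfg = CohortConfig(
            n_timepoints=config.n_timepoints,
            sampling_interval=config.sampling_interval,
            seed=config.seed,
        )
        series, covariates, truth = simulate_cohort(spec, cohort_cfg, atlas)
        write_cohort(outdir / "cohort", series, covariates, atlas, truth)
    elif config.manifest_path:
        series, covariates = read_manifest(config.manifest_path, atlas, config.sampling_interval)
    else:
        raise ValueError("config must either simulate or point at a manifest")

    stack = build_stack(series, covariates, atlas, config)

    zdir = outdir / "matrices"
    zdir.mkdir(exist_ok=True)
    for k in range(stack.n_subjects):
        sid = stack.covariates.iloc[k]["subject_id"]
        write_matrix(zdir / f"{sid}_z.tsv", stack.z[k], atlas.names)

    results = analyze_cohort(stack, config)
    for g, m in results["mean_abs"].items():
        write_matrix(outdir / f"mean_abs_{g}.tsv", m, atlas.names)
    for name, m in results["differences"].items():
        write_matrix(outdir / f"diff_{name}.tsv", m, atlas.names)
    results["altered"].to_csv(outdir / "altered_edges.csv", index=False, float_format=_FLOAT_FMT)
    results["cognition"].to_csv(outdir / "cognition.csv", index=False, float_format=_FLOAT_FMT)

    anova = results["anova"]
    summary = {
        "anova": {k: v for k, v in anova.items() if k != "posthoc"},
        "anova_posthoc": anova["posthoc"].to_dict(orient="records"),
        "altered_summary": results["summary"],
        "cognition_report": results["cognition_report"],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    provenance = {
        "package": "connectograph",
        "version": __version__,
        "config": config.to_dict(),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    results["stack"] = stack
    return results
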