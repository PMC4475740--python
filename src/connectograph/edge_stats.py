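"""Edge-wise group statistics and dual-criterion altered-edge selection.

An edge is declared "altered" between a control and a patient group only if
it passes both of two criteria:

(a) its Fisher-z values are significantly nonzero within at least one of the
    two groups (one-sample two-tailed t-test, Bonferroni-corrected over all
    N(N-1)/2 edges within each group), and
(b) its z values differ significantly between the groups (two-sample
    two-tailed t-test, Benjamini-Hochberg FDR-corrected over all edges).

Criterion (a) guards against declaring differences between two edges that
are indistinguishable from noise in both groups; criterion (b) supplies the
between-group contrast with false-discovery-rate control over the full edge
family.  Direction is "decreased" when the control group's mean z exceeds
the patient group's.

The two-sample test defaults to the classical pooled-variance Student's t
(df = nA + nB - 2); Welch's unequal-variance form is available via
``equal_var=False``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import Atlas, classify_edge, edge_count
from .connectome import CohortStack, mean_connectivity_strength

__all__ = [
    "one_sample_edge_tests",
    "bonferroni_mask",
    "two_sample_edge_tests",
    "bh_fdr",
    "select_altered_edges",
    "summarize_altered",
    "group_strength_anova",
]

logger = logging.getLogger(__name__)


def _edge_frame(atlas: Atlas) -> pd.DataFrame:
    edges = atlas.edges()
    return pd.DataFrame({"i": edges[:, 0], "j": edges[:, 1]})


def _degenerate_p(means: np.ndarray) -> np.ndarray:
    """Limit p-values for zero-variance edges: 0 if the mean is nonzero, 1 if zero."""
    return np.where(means == 0.0, 1.0, 0.0)


def one_sample_edge_tests(stack: CohortStack, group: str) -> pd.DataFrame:
    """Per-edge one-sample two-tailed t-test of mean z against zero.

    Returns a frame with columns ``i, j, t, p, df`` over all upper-triangle
    edges.  Zero-variance edges get limit p-values (0 for nonzero mean, 1 for
    zero mean) and are logged rather than crashing the pipeline.
    """
    x = stack.edge_values(group)
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"group {group!r} needs >= 3 subjects for a one-sample test, has {n}")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    df = n - 1
    out = _edge_frame(stack.atlas)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d zero-variance edges in one-sample test for %s", degenerate.sum(), group)
        with np.errstate(invalid="ignore"):
            t[degenerate] = np.sign(mean[degenerate]) * np.inf
        t[degenerate & (mean == 0)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[degenerate] = _degenerate_p(mean[degenerate])
    out["t"], out["p"], out["df"] = t, p, df
    out.attrs["comparison"] = f"one_sample:{group}"
    return out


def bonferroni_mask(tests: pd.DataFrame | np.ndarray, alpha: float = 0.05, m: int | None = None) -> np.ndarray:
    """Familywise Bonferroni rejection mask: p < alpha / m.

    ``m`` defaults to the number of tests supplied (for a whole-brain edge
    family that is N(N-1)/2).
    """
    p = tests["p"].to_numpy() if isinstance(tests, pd.DataFrame) else np.asarray(tests, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return p < alpha / m


def two_sample_edge_tests(
    stack: CohortStack, group_a: str, group_b: str, equal_var: bool = True
) -> pd.DataFrame:
    """Per-edge two-sample two-tailed t-test between groups (A minus B).

    Pooled-variance Student's t with df = nA + nB - 2 by default; Welch's
    t-test (Satterthwaite df) when ``equal_var=False``.  The sign of t
    encodes direction: positive means group A's mean z is larger.
    """
    xa, xb = stack.edge_values(group_a), stack.edge_values(group_b)
    na, nb = xa.shape[0], xb.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("both groups need >= 2 subjects for a two-sample test")
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    va, vb = xa.var(axis=0, ddof=1), xb.var(axis=0, ddof=1)
    diff = ma - mb
    if equal_var:
        df = np.full(diff.shape, float(na + nb - 2))
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        df = np.where(np.isfinite(df), df, float(na + nb - 2))
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    if degenerate.any():
        logger.warning(
            "%d zero-pooled-variance edges in %s vs %s two-sample test",
            degenerate.sum(), group_a, group_b,
        )
        with np.errstate(invalid="ignore"):
            t[degenerate] = np.sign(diff[degenerate]) * np.inf
        t[degenerate & (diff == 0)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[degenerate] = _degenerate_p(diff[degenerate])
    out = _edge_frame(stack.atlas)
    out["t"], out["p"], out["df"] = t, p, df
    out.attrs["comparison"] = f"two_sample:{group_a}_vs_{group_b}"
    return out


def bh_fdr(p_values: np.ndarray | list[float], q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up procedure at level q.

    Returns the rejection mask (original order) and the critical p — the
    largest rejected p-value, or 0.0 when nothing is rejected.  Ties share
    their fate: equal p-values are rejected or retained together.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mask = multipletests(p, alpha=q, method="fdr_bh")[0]
    critical = float(p[mask].max()) if mask.any() else 0.0
    return mask, critical


def select_altered_edges(
    stack: CohortStack,
    control: str,
    patient: str,
    alpha_one: float = 0.05,
    q_two: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Dual-criterion altered-edge table between a control and a patient group.

    An edge is included iff (a) its one-sample Bonferroni mask is true in the
    control OR the patient group (m = edge count within each group
    separately), and (b) its two-sample BH-FDR mask over all edges is true.

    Returns a frame with one row per altered edge: indices, region names,
    test statistics, the FDR critical p, direction (decreased when the
    control mean z exceeds the patient mean z), per-group criterion-(a)
    flags, and lobe/hemisphere classification.
    """
    m = edge_count(stack.atlas)
    one_c = one_sample_edge_tests(stack, control)
    one_p = one_sample_edge_tests(stack, patient)
    mask_a = bonferroni_mask(one_c, alpha_one, m) | bonferroni_mask(one_p, alpha_one, m)
    two = two_sample_edge_tests(stack, control, patient, equal_var=equal_var)
    mask_b, critical = bh_fdr(two["p"].to_numpy(), q_two)
    selected = mask_a & mask_b

    mean_c = stack.edge_values(control).mean(axis=0)
    mean_p = stack.edge_values(patient).mean(axis=0)
    rows = two.loc[selected, ["i", "j", "t", "p", "df"]].reset_index(drop=True)
    idx = np.flatnonzero(selected)
    names = stack.atlas.names
    rows.insert(2, "region_i", [names[i] for i in rows["i"]])
    rows.insert(3, "region_j", [names[j] for j in rows["j"]])
    rows["q_threshold"] = critical
    rows["direction"] = np.where(mean_c[idx] > mean_p[idx], "decreased", "increased")
    rows["passed_control"] = bonferroni_mask(one_c, alpha_one, m)[idx]
    rows["passed_patient"] = bonferroni_mask(one_p, alpha_one, m)[idx]
    classes = [classify_edge(stack.atlas, int(i), int(j)) for i, j in zip(rows["i"], rows["j"])]
    rows["lobe_class"] = [c[0] for c in classes]
    rows["hemisphere_class"] = [c[1] for c in classes]
    rows.attrs["comparison"] = f"{control}_vs_{patient}"
    rows.attrs["q_critical"] = critical
    return rows


def summarize_altered(edges: pd.DataFrame, atlas: Atlas) -> dict:
    """Topology summary of an altered-edge table.

    Returns node degrees among altered edges (ranked), endpoint counts per
    lobe, and the interlobe/intralobe x interhemispheric/intrahemispheric
    tallies; the lobe tallies partition the total edge count.
    """
    names = atlas.names
    degree = {name: 0 for name in names}
    lobe_counts: dict[str, int] = {}
    tallies = {
        ("interlobe", "interhemispheric"): 0,
        ("interlobe", "intrahemispheric"): 0,
        ("intralobe", "interhemispheric"): 0,
        ("intralobe", "intrahemispheric"): 0,
    }
    for _, row in edges.iterrows():
        i, j = int(row["i"]), int(row["j"])
        degree[names[i]] += 1
        degree[names[j]] += 1
        for k in (i, j):
            lobe = atlas.regions[k].lobe
            lobe_counts[lobe] = lobe_counts.get(lobe, 0) + 1
        tallies[classify_edge(atlas, i, j)] += 1
    ranked = sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))
    return {
        "n_altered": int(len(edges)),
        "node_degree": {name: d for name, d in ranked if d > 0},
        "top_nodes": [name for name, d in ranked[:10] if d > 0],
        "lobe_endpoint_counts": dict(sorted(lobe_counts.items())),
        "tallies": {
            "interlobe": tallies[("interlobe", "interhemispheric")]
            + tallies[("interlobe", "intrahemispheric")],
            "intralobe": tallies[("intralobe", "interhemispheric")]
            + tallies[("intralobe", "intrahemispheric")],
            "interhemispheric": tallies[("interlobe", "interhemispheric")]
            + tallies[("intralobe", "interhemispheric")],
            "intrahemispheric": tallies[("interlobe", "intrahemispheric")]
            + tallies[("intralobe", "intrahemispheric")],
        },
    }


def group_strength_anova(stack: CohortStack, absolute: bool = True, equal_var: bool = True) -> dict:
    """One-way ANOVA on per-subject mean connectivity strength across groups.

    Returns F, df1 = k-1, df2 = N-k, p, the per-group mean strengths, and a
    pairwise post hoc table of two-sample t-tests.  A degenerate cohort in
    which every subject has identical strength yields F = 0, p = 1 (logged).
    """
    groups = stack.groups
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for ANOVA")
    strengths = {
        g: np.array([mean_connectivity_strength(z, absolute=absolute) for z in stack.group_z(g)])
        for g in groups
    }
    for g, s in strengths.items():
        if s.size < 2:
            raise ValueError(f"group {g!r} needs >= 2 subjects")
    samples = list(strengths.values())
    n_total = sum(s.size for s in samples)
    df1, df2 = len(groups) - 1, n_total - len(groups)
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        logger.warning("all subjects have identical strength; ANOVA degenerate")
        f_stat, p = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f_stat, p = stats.f_oneway(*samples)
        if not np.isfinite(f_stat):
            logger.warning("degenerate ANOVA (zero within-group variance)")
            f_stat, p = np.inf, 0.0
    posthoc = []
    for a_idx in range(len(groups)):
        for b_idx in range(a_idx + 1, len(groups)):
            a, b = groups[a_idx], groups[b_idx]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                t, pt = stats.ttest_ind(strengths[a], strengths[b], equal_var=equal_var)
            posthoc.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "t": float(t),
                    "p": float(pt),
                    "df": strengths[a].size + strengths[b].size - 2,
                }
            )
    return {
        "F": float(f_stat),
        "df1": int(df1),
        "df2": int(df2),
        "p": float(p),
        "group_means": {g: float(s.mean()) for g, s in strengths.items()},
        "posthoc": pd.DataFrame(posthoc),
    }
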