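"""Edge strength versus cognition: MMSE correlation among altered edges.

For each altered edge, the Pearson correlation between subjects' Fisher-z
connectivity at that edge and their MMSE score is computed over a pooled set
of groups (typically the patient groups, singly and combined).  The p-values
are deliberately uncorrected (alpha 0.05) — this stage is exploratory
bookkeeping over a small pre-selected edge set, and the report header says
so.  A positive correlation means weaker connectivity goes with a lower
(more impaired) score.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import CohortStack

__all__ = ["edge_mmse_correlation", "correlation_report", "REPORT_HEADER"]

logger = logging.getLogger(__name__)

REPORT_HEADER = (
    "Edge strength vs MMSE: exploratory Pearson correlations, "
    "p-values uncorrected for multiple comparisons"
)


def edge_mmse_correlation(
    stack: CohortStack,
    edges: pd.DataFrame,
    groups: Sequence[str] = ("MCI", "AD"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation between per-edge z and MMSE over pooled groups.

    ``edges`` is an altered-edge table with ``i``/``j`` columns.  Subjects
    from all listed groups are pooled (the combined-group correlation is
    computed on pooled subjects, never by averaging per-group r).  Returns a
    frame with r, two-tailed p, n, a ``significant`` flag (p < alpha) and
    ``significant_positive`` (r > 0 and p < alpha).  Constant MMSE makes r
    undefined; such rows are flagged not-significant with r = NaN and logged.
    """
    if "mmse" not in stack.covariates.columns:
        raise ValueError("covariates have no 'mmse' column")
    sel = stack.covariates["group"].isin(list(groups)).to_numpy()
    if sel.sum() < 3:
        raise ValueError(f"need >= 3 subjects in groups {list(groups)}, have {int(sel.sum())}")
    mmse = stack.covariates.loc[sel, "mmse"]
    missing = stack.covariates.loc[sel & stack.covariates["mmse"].isna().to_numpy(), "subject_id"]
    if len(missing):
        raise ValueError(f"subjects missing MMSE: {list(missing)}")
    mmse = mmse.to_numpy(dtype=float)
    n = mmse.size
    group_label = "+".join(groups)
    rows = []
    constant = np.ptp(mmse) == 0
    if constant:
        logger.warning("MMSE constant across %s subjects; correlations undefined", group_label)
    for _, edge in edges.iterrows():
        i, j = int(edge["i"]), int(edge["j"])
        z = stack.z[sel, i, j]
        if constant or np.ptp(z) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(z, mmse)
        rows.append(
            {
                "i": i,
                "j": j,
                "region_i": stack.atlas.names[i],
                "region_j": stack.atlas.names[j],
                "group_set": group_label,
                "r": float(r) if np.isfinite(r) else np.nan,
                "p": float(p) if np.isfinite(p) else np.nan,
                "n": n,
            }
        )
    out = pd.DataFrame(
        rows, columns=["i", "j", "region_i", "region_j", "group_set", "r", "p", "n"]
    )
    out["significant"] = (out["p"] < alpha).fillna(False)
    out["significant_positive"] = out["significant"] & (out["r"] > 0)
    out.attrs["alpha"] = alpha
    out.attrs["header"] = REPORT_HEADER
    return out


def correlation_report(correlations: pd.DataFrame) -> dict:
    """Bookkeeping per group set: totals, significant-positive/negative counts,
    and the headline edge (largest |r|)."""
    report: dict = {"header": REPORT_HEADER, "group_sets": {}}
    if len(correlations) == 0:
        return report
    for group_set, sub in correlations.groupby("group_set"):
        n_pos = int(sub["significant_positive"].sum())
        n_neg = int((sub["significant"] & (sub["r"] < 0)).sum())
        finite = sub.dropna(subset=["r"])
        headline = None
        if len(finite):
            best = finite.loc[finite["r"].abs().idxmax()]
            headline = {
                "region_i": best["region_i"],
                "region_j": best["region_j"],
                "r": float(best["r"]),
                "p": float(best["p"]),
            }
        report["group_sets"][group_set] = {
            "total_altered": int(len(sub)),
            "significant_positive": n_pos,
            "significant_negative": n_neg,
            "headline_edge": headline,
        }
    return report
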