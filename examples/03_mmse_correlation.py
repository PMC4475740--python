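"""Correlate altered-edge strength with MMSE in the patient groups.

For each altered edge, computes the Pearson correlation between subjects'
Fisher-z connectivity and their MMSE score, in MCI, AD, and the pooled
MCI+AD set (uncorrected p < 0.05, exploratory).
Run:  python examples/03_mmse_correlation.py
"""

from connectograph import (
    CohortConfig,
    RunConfig,
    build_stack,
    correlation_report,
    default_atlas,
    default_spec,
    edge_mmse_correlation,
    select_altered_edges,
    simulate_cohort,
)

atlas = default_atlas()
series, covariates, _ = simulate_cohort(default_spec(atlas), CohortConfig(seed=0), atlas)
stack = build_stack(series, covariates, atlas, RunConfig())
altered = select_altered_edges(stack, "NC", "AD")

import pandas as pd

tables = [
    edge_mmse_correlation(stack, altered, groups=gset)
    for gset in (["MCI"], ["AD"], ["MCI", "AD"])
]
report = correlation_report(pd.concat(tables, ignore_index=True))

print(report["header"])
for group_set, entry in report["group_sets"].items():
    head = entry["headline_edge"]
    print(f"{group_set:>6}: {entry['significant_positive']}/{entry['total_altered']} "
          f"significantly positive; strongest edge "
          f"{head['region_i']}-{head['region_j']} (r={head['r']:.2f}, p={head['p']:.2g})")
# Positive correlations mean weaker connectivity goes with lower (more
# impaired) MMSE; the pooled patient group has the most power because it
# spans the widest severity range.
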