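import numpy as np
import pandas as pd
import pytest

from connectograph.atlas import Atlas, atlas_from_frame
from connectograph.connectome import CohortStack


def make_toy_atlas(n_base: int, lobes: list[str]) -> Atlas:
    """Bilateral toy atlas: n_base homologous region pairs cycled over lobes."""
    rows = []
    for k in range(n_base):
        for hemi in ("left", "right"):
            idx = len(rows)
            rows.append(
                dict(
                    index=idx,
                    label_value=idx + 1,
                    abbreviation=f"R{k}",
                    hemisphere=hemi,
                    lobe=lobes[k % len(lobes)],
                )
            )
    return atlas_from_frame(pd.DataFrame(rows))


def stack_from_edges(edge_values: np.ndarray, covariates: pd.DataFrame, atlas: Atlas) -> CohortStack:
    """Build a cohort stack from a subjects x edges array of z values."""
    n = atlas.n_regions
    iu = np.triu_indices(n, k=1)
    z = np.zeros((edge_values.shape[0], n, n))
    z[:, iu[0], iu[1]] = edge_values
    z[:, iu[1], iu[0]] = edge_values
    return CohortStack(z, covariates, atlas)


def covariate_frame(group_sizes: dict[str, int], mmse: np.ndarray | None = None) -> pd.DataFrame:
    rows = []
    for g, n in group_sizes.items():
        for k in range(n):
            rows.append({"subject_id": f"{g}{k:03d}", "group": g})
    frame = pd.DataFrame(rows)
    frame["mmse"] = mmse if mmse is not None else 25
    return frame


@pytest.fixture(scope="session")
def atlas6() -> Atlas:
    """Six regions: 3 bilateral pairs over 2 lobes."""
    return make_toy_atlas(3, ["frontal", "temporal"])


@pytest.fixture(scope="session")
def atlas20() -> Atlas:
    """Twenty regions: 10 bilateral pairs over 3 lobes."""
    return make_toy_atlas(10, ["frontal", "temporal", "parietal"])
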