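"""Region catalogue, node ordering, and edge indexing for parcellation connectomes.

Every matrix produced downstream (per-subject Fisher-z connectivity, group means,
difference maps) uses the node order defined here: 0-based contiguous indices in
atlas-file order.  Edges are unordered region pairs (i, j) with i < j — the upper
triangle excluding the diagonal — so a 90-region parcellation yields
90 x 89 / 2 = 4005 distinct edges.

The bundled default atlas mirrors the 90-region automated anatomical labeling
(AAL) scheme: 45 homologous regions per hemisphere with a conventional lobe
grouping (frontal, limbic, occipital, parietal, subcortical, temporal).  Lobe
vocabulary is an open enumeration read from the atlas file, so alternative
parcellations and lobe groupings work unmodified.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "Atlas",
    "AtlasError",
    "load_atlas",
    "default_atlas",
    "edge_count",
    "classify_edge",
]

HEMISPHERES = frozenset({"left", "right"})

REQUIRED_COLUMNS = ("index", "label_value", "abbreviation", "hemisphere", "lobe")


class AtlasError(ValueError):
    """Raised when an atlas table violates its invariants."""


@dataclass(frozen=True)
class Region:
    """One parcellation region (a network node).

    Parameters
    ----------
    index : int
        0-based node position; defines matrix row/column order.
    label_value : int
        Positive integer code identifying the region in label images.
    abbreviation : str
        Short name, e.g. ``PCC`` or ``SFGmed``.  Homologous regions in the
        two hemispheres share the abbreviation.
    hemisphere : str
        ``"left"`` or ``"right"``.
    lobe : str
        Lobe label, e.g. ``"temporal"``; open vocabulary.
    """

    index: int
    label_value: int
    abbreviation: str
    hemisphere: str
    lobe: str

    @property
    def name(self) -> str:
        return f"{self.abbreviation}.{'L' if self.hemisphere == 'left' else 'R'}"


@dataclass(frozen=True)
class Atlas:
    """Ordered region catalogue shared by all pipeline stages."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        idx = [r.index for r in self.regions]
        if idx != list(range(len(self.regions))):
            raise AtlasError(
                "region indices must be contiguous 0..N-1 in file order; got "
                f"{idx[:10]}{'...' if len(idx) > 10 else ''}"
            )
        seen: dict[int, int] = {}
        for r in self.regions:
            if r.label_value <= 0:
                raise AtlasError(f"row {r.index}: label_value must be positive, got {r.label_value}")
            if r.label_value in seen:
                raise AtlasError(
                    f"row {r.index}: duplicate label_value {r.label_value} "
                    f"(first used in row {seen[r.label_value]})"
                )
            seen[r.label_value] = r.index
            if r.hemisphere not in HEMISPHERES:
                raise AtlasError(f"row {r.index}: unknown hemisphere token {r.hemisphere!r}")
            if not r.lobe or not isinstance(r.lobe, str):
                raise AtlasError(f"row {r.index}: invalid lobe token {r.lobe!r}")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    @property
    def label_values(self) -> np.ndarray:
        return np.array([r.label_value for r in self.regions], dtype=int)

    def edges(self) -> np.ndarray:
        """All (i, j) pairs with i < j, row-major over the upper triangle; shape (m, 2)."""
        iu = np.triu_indices(self.n_regions, k=1)
        return np.column_stack(iu)

    def find(self, abbreviation: str, hemisphere: str) -> Region:
        for r in self.regions:
            if r.abbreviation == abbreviation and r.hemisphere == hemisphere:
                return r
        raise KeyError(f"no region {abbreviation!r} in hemisphere {hemisphere!r}")

    def homologue_pairs(self) -> list[tuple[int, int]]:
        """Index pairs of interhemispheric homologues (same abbreviation, opposite side)."""
        by_abbr: dict[str, dict[str, int]] = {}
        for r in self.regions:
            by_abbr.setdefault(r.abbreviation, {})[r.hemisphere] = r.index
        pairs = []
        for sides in by_abbr.values():
            if len(sides) == 2:
                i, j = sorted(sides.values())
                pairs.append((i, j))
        return pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [r.index for r in self.regions],
                "label_value": [r.label_value for r in self.regions],
                "abbreviation": [r.abbreviation for r in self.regions],
                "hemisphere": [r.hemisphere for r in self.regions],
                "lobe": [r.lobe for r in self.regions],
            }
        )


def load_atlas(path: str | Path) -> Atlas:
    """Load an atlas table (TSV or CSV with header) and validate its invariants.

    Required columns: ``index, label_value, abbreviation, hemisphere, lobe``.
    Region order is preserved as file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t" if path.suffix.lower() in {".tsv", ".txt"} else ",")
    return atlas_from_frame(table)


def atlas_from_frame(table: pd.DataFrame) -> Atlas:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise AtlasError(f"atlas table missing required columns: {missing}")
    regions = tuple(
        Region(
            index=int(row["index"]),
            label_value=int(row["label_value"]),
            abbreviation=str(row["abbreviation"]),
            hemisphere=str(row["hemisphere"]),
            lobe=str(row["lobe"]),
        )
        for _, row in table.iterrows()
    )
    return Atlas(regions)


def default_atlas() -> Atlas:
    """The bundled 90-region (45 per hemisphere) AAL-style atlas."""
    with resources.files("connectograph.data").joinpath("aal90.tsv").open("r") as fh:
        table = pd.read_csv(fh, sep="\t")
    return atlas_from_frame(table)


def edge_count(atlas: Atlas | int) -> int:
    """Number of distinct edges N(N-1)/2 for an atlas (or an integer region count)."""
    n = atlas if isinstance(atlas, int) else atlas.n_regions
    return n * (n - 1) // 2


def classify_edge(atlas: Atlas, i: int, j: int) -> tuple[str, str]:
    """Classify an edge by lobe and hemisphere membership of its endpoints.

    Returns
    -------
    (lobe_class, hemisphere_class)
        ``lobe_class`` is ``"interlobe"`` iff the two lobe labels differ, else
        ``"intralobe"``; ``hemisphere_class`` is ``"interhemispheric"`` iff the
        hemispheres differ, else ``"intrahemispheric"``.  Symmetric in (i, j).
    """
    n = atlas.n_regions
    for k in (i, j):
        if not 0 <= k < n:
            raise IndexError(f"region index {k} out of range for {n}-region atlas")
    a, b = atlas.regions[i], atlas.regions[j]
    lobe_class = "intralobe" if a.lobe == b.lobe else "interlobe"
    hemi_class = "intrahemispheric" if a.hemisphere == b.hemisphere else "interhemispheric"
    return lobe_class, hemi_class
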