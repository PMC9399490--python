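"""Parcellation, large-scale network labels, and canonical edge indexing.

A parcellation is an ordered list of brain regions; the full atlas used
throughout this package follows the HCP-MMP1 convention extended with
subcortex: 180 cortical parcels per hemisphere, 9 subcortical structures per
hemisphere, and the brainstem — 379 regions in total.  Functional
connectivity between R regions forms a symmetric correlation matrix; since
corr(i, j) == corr(j, i) and the diagonal is identically 1, the package
works on the R*(R-1)/2 unique off-diagonal edges (71,631 for R = 379, the
unordered form of the 379**2 = 143,641 ordered correlations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Network labels of the nine named large-scale networks; regions outside
#: any named network (by convention the subcortex and brainstem) carry OTHER.
NETWORK_LABELS = (
    "AccessoryLanguage",
    "DMN",
    "CEN",
    "DAN",
    "Language",
    "LimbicParalimbic",
    "SN",
    "SMN",
    "VN",
)
OTHER_NETWORK = "OTHER"

HEMISPHERES = ("L", "R", "NONE")

PARCELLATION_COLUMNS = ("region_id", "region_name", "hemisphere", "network")


class ParcellationError(ValueError):
    """Raised when a parcellation table violates its invariants."""


@dataclass(frozen=True)
class Region:
    region_id: int
    region_name: str
    hemisphere: str
    network: str


@dataclass(frozen=True)
class Parcellation:
    """Ordered, validated list of regions with network affiliations.

    Region ids are 0-based, unique and contiguous; matrix rows/columns must
    follow this order.
    """

    regions: tuple[Region, ...]
    _network_of: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if sorted(ids) != list(range(len(ids))):
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                raise ParcellationError(f"duplicate region_id(s): {sorted(dupes)}")
            raise ParcellationError("region_ids must be contiguous from 0")
        if ids != list(range(len(ids))):
            raise ParcellationError("regions must be ordered by region_id")
        for r in self.regions:
            if r.hemisphere not in HEMISPHERES:
                raise ParcellationError(
                    f"region {r.region_id}: hemisphere {r.hemisphere!r} "
                    f"not in {HEMISPHERES}"
                )
            if not r.network:
                raise ParcellationError(f"region {r.region_id}: empty network label")
        object.__setattr__(
            self, "_network_of", np.array([r.network for r in self.regions], dtype=object)
        )

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def networks(self) -> tuple[str, ...]:
        """Distinct network labels in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.network, None)
        return tuple(seen)

    def network_of(self, region_id: int) -> str:
        if not 0 <= region_id < self.n_regions:
            raise ParcellationError(f"unknown region_id {region_id}")
        return self.regions[region_id].network

    def network_array(self) -> np.ndarray:
        """Network label per region as an object array (vectorized access)."""
        return self._network_of

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [r.region_id for r in self.regions],
                "region_name": [r.region_name for r in self.regions],
                "hemisphere": [r.hemisphere for r in self.regions],
                "network": [r.network for r in self.regions],
            }
        )


@dataclass(frozen=True)
class EdgeIndex:
    """Canonical row-major ordering of the unordered region pairs (i, j), i < j.

    The linear index of (i, j) is ``i*(2R - i - 1)//2 + (j - i - 1)`` — the
    order produced by ``numpy.triu_indices(R, k=1)``.
    """

    n_regions: int
    row: np.ndarray  # i endpoints, shape (E,)
    col: np.ndarray  # j endpoints, shape (E,)

    @property
    def n_edges(self) -> int:
        return self.row.shape[0]

    @property
    def n_ordered_correlations(self) -> int:
        """Count of ordered region pairs including the diagonal (R**2)."""
        return self.n_regions * self.n_regions

    def index_of(self, i: int, j: int) -> int:
        """Linear index of the unordered pair {i, j} (order-insensitive)."""
        if i == j:
            raise ValueError("self-edges are not indexed")
        if not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
            raise ValueError(f"region pair ({i}, {j}) out of range")
        if i > j:
            i, j = j, i
        r = self.n_regions
        return i * (2 * r - i - 1) // 2 + (j - i - 1)

    def pairs(self) -> Iterable[tuple[int, int]]:
        return zip(self.row.tolist(), self.col.tolist())

    def edge_values(self, matrix: np.ndarray) -> np.ndarray:
        """Extract the upper-triangle edge vector of a symmetric matrix."""
        m = np.asarray(matrix, dtype=float)
        if m.shape != (self.n_regions, self.n_regions):
            raise ValueError(
                f"matrix shape {m.shape} does not match {self.n_regions} regions"
            )
        return m[self.row, self.col]


def build_edge_index(parc: Parcellation | int) -> EdgeIndex:
    """Canonical edge index over a parcellation (or an explicit region count)."""
    r = parc if isinstance(parc, int) else parc.n_regions
    if r < 2:
        raise ValueError("need at least 2 regions to form edges")
    row, col = np.triu_indices(r, k=1)
    return EdgeIndex(n_regions=r, row=row, col=col)


def edge_networks(edge: tuple[int, int], parc: Parcellation) -> frozenset[str]:
    """Distinct network labels of an edge's two endpoints.

    A within-network edge yields a singleton set; a cross-network edge yields
    both labels.  Symmetric in the endpoints.
    """
    i, j = edge
    return frozenset((parc.network_of(i), parc.network_of(j)))


def load_parcellation(path: str | Path) -> Parcellation:
    """Read a parcellation TSV (columns region_id, region_name, hemisphere, network).

    Unknown network strings are preserved verbatim; empty network cells
    become OTHER.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PARCELLATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParcellationError(f"{path}: missing column(s) {missing}")
    try:
        ids = df["region_id"].astype(int)
    except ValueError as exc:
        raise ParcellationError(f"{path}: non-integer region_id") from exc
    regions = tuple(
        Region(
            region_id=int(i),
            region_name=str(name),
            hemisphere=str(hemi) if hemi else "NONE",
            network=str(net) if net else OTHER_NETWORK,
        )
        for i, name, hemi, net in zip(
            ids, df["region_name"], df["hemisphere"], df["network"]
        )
    )
    return Parcellation(regions=regions)


def write_parcellation(parc: Parcellation, path: str | Path) -> None:
    parc.to_frame().to_csv(path, sep="\t", index=False)


def default_parcellation() -> Parcellation:
    """The full 379-region atlas: 180 cortical parcels per hemisphere split
    evenly over the nine named networks (20 parcels each), 9 subcortical
    structures per hemisphere and the brainstem labelled OTHER.

    The cortical network assignment is a deterministic block layout — it
    stands in for the anatomical lookup of a real atlas and is sufficient
    for every network-level aggregation the package performs.
    """
    regions: list[Region] = []
    rid = 0
    for hemi in ("L", "R"):
        for k in range(180):
            network = NETWORK_LABELS[k // 20]
            regions.append(
                Region(rid, f"{hemi}_CTX_{k:03d}", hemi, network)
            )
            rid += 1
    subcortical = (
        "Thalamus", "Caudate", "Putamen", "Pallidum", "Hippocampus",
        "Amygdala", "Accumbens", "VentralDC", "Cerebellum",
    )
    for hemi in ("L", "R"):
        for name in subcortical:
            regions.append(Region(rid, f"{hemi}_{name}", hemi, OTHER_NETWORK))
            rid += 1
    regions.append(Region(rid, "Brainstem", "NONE", OTHER_NETWORK))
    return Parcellation(regions=tuple(regions))


def synthetic_parcellation(n_regions: int) -> Parcellation:
    """Reduced atlas for simulation and tests: the nine named networks are
    cycled over the first ``n_regions - 1`` regions (left/right alternating),
    and the last region is an OTHER-labelled brainstem stand-in."""
    if n_regions == 379:
        return default_parcellation()
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    regions = []
    for k in range(n_regions - 1):
        hemi = "L" if k % 2 == 0 else "R"
        network = NETWORK_LABELS[k % len(NETWORK_LABELS)]
        regions.append(Region(k, f"{hemi}_CTX_{k:03d}", hemi, network))
    regions.append(Region(n_regions - 1, "Brainstem", "NONE", OTHER_NETWORK))
    return Parcellation(regions=tuple(regions))
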