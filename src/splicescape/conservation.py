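"""Cross-strain junction conservation and the splicing phylogeny.

Strain junction sets are merged on strand-less intron coordinates into
per-junction coverage profiles.  From the profiles we compute conservation
summaries at coverage thresholds, the pairwise shared-junction matrix, and
a hierarchical clustering of strains ("splicing phylogeny"): each strain is
represented by its row of shared-junction counts, strains are compared by
Euclidean distance between those rows, and merged agglomeratively
(average linkage by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist

from .junctions import CONFLICT, JunctionKey, MINUS, PLUS, StrainJunctionSet, UNDEFINED


@dataclass(slots=True)
class ConservationProfile:
    """Presence/coverage of one junction across the strain panel."""

    key: JunctionKey
    strains: tuple[str, ...]
    coverage: np.ndarray  # unique reads per strain, 0 = absent
    reconciled_strand: str

    def n_strains_present(self, t: int = 1) -> int:
        return int((self.coverage >= t).sum())


def merge_strains(sets: Sequence[StrainJunctionSet]) -> list[ConservationProfile]:
    """Union strain junction sets into per-junction coverage profiles.

    Strand reconciliation: the unique non-undefined strand observed across
    strains; ``.`` if none; ``conflict`` (kept, flagged) if both orientations
    were observed.
    """
    if len(sets) < 2:
        raise ValueError("merge requires at least 2 strain sets")
    labels = tuple(s.strain for s in sets)
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate strain labels in {labels}")
    all_keys: set[JunctionKey] = set()
    for s in sets:
        all_keys.update(s.junctions)
    profiles = []
    for key in sorted(all_keys):
        coverage = np.zeros(len(sets), dtype=np.int64)
        strands = set()
        for i, s in enumerate(sets):
            j = s.junctions.get(key)
            if j is not None:
                coverage[i] = j.unique_reads
                if j.strand in (PLUS, MINUS):
                    strands.add(j.strand)
        if not strands:
            strand = UNDEFINED
        elif len(strands) == 1:
            strand = strands.pop()
        else:
            strand = CONFLICT
        profiles.append(ConservationProfile(key, labels, coverage, strand))
    return profiles


def conservation_summary(
    profiles: Sequence[ConservationProfile],
    thresholds: Iterable[int] = (1, 3, 10),
    mode: Literal["per-strain", "focal"] = "focal",
) -> pd.DataFrame:
    """Fractions of junctions shared by >= 2 strains and by all strains.

    For each threshold t the universe is every junction with coverage >= t
    in at least one strain.  In ``focal`` mode (default) the threshold
    gates the universe only and presence in a strain counts at
    coverage >= 1; in ``per-strain`` mode a strain counts as carrying the
    junction only at coverage >= t.  The focal reading is the default
    because it is the one under which the shared fractions of a
    low-coverage-dominated landscape rise monotonically with the
    threshold, the behaviour reported for deep brain RNA-seq panels; the
    symmetric per-strain reading is kept as an option.  Empty universes
    yield NaN fractions.
    """
    thresholds = list(thresholds)
    if any(t < 1 for t in thresholds):
        raise ValueError("thresholds must be >= 1")
    rows = []
    if profiles:
        cov = np.vstack([p.coverage for p in profiles])
        n_strains = cov.shape[1]
    for t in thresholds:
        if not profiles:
            rows.append((t, 0, 0, np.nan, 0, np.nan))
            continue
        if mode == "per-strain":
            present = cov >= t
        elif mode == "focal":
            present = (cov >= 1) & (cov.max(axis=1, keepdims=True) >= t)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        counts = present.sum(axis=1)
        universe = counts >= 1
        n_universe = int(universe.sum())
        n_shared2 = int((counts >= 2).sum())
        n_all = int((counts == n_strains).sum())
        rows.append(
            (
                t,
                n_universe,
                n_shared2,
                n_shared2 / n_universe if n_universe else np.nan,
                n_all,
                n_all / n_universe if n_universe else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "threshold",
            "universe",
            "n_shared_ge2",
            "frac_shared_ge2",
            "n_all_strains",
            "frac_all_strains",
        ],
    )


@dataclass
class SharingMatrix:
    """Pairwise counts of junctions carried by both strains at threshold t."""

    strains: tuple[str, ...]
    shared: np.ndarray  # N x N symmetric, diagonal = per-strain totals
    threshold: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.shared, index=self.strains, columns=self.strains)


def sharing_matrix(profiles: Sequence[ConservationProfile], t: int = 1) -> SharingMatrix:
    if t < 1:
        raise ValueError("threshold must be >= 1")
    if not profiles:
        raise ValueError("no profiles to tabulate")
    strains = profiles[0].strains
    present = np.vstack([p.coverage >= t for p in profiles]).astype(np.int64)
    shared = present.T @ present
    return SharingMatrix(strains, shared, t)


@dataclass
class Phylogeny:
    """Strain dendrogram from shared-junction counts."""

    labels: tuple[str, ...]  # label-sorted leaf order used for clustering
    linkage: np.ndarray  # scipy linkage matrix
    newick: str

    def leaf_divergence(self) -> pd.Series:
        """Mean cophenetic distance from each leaf to all other leaves.

        The most divergent strains (outermost dendrogram branches) rank
        highest.
        """
        from scipy.spatial.distance import squareform

        dmat = squareform(cophenet(self.linkage))
        n = len(self.labels)
        means = dmat.sum(axis=1) / (n - 1)
        return pd.Series(means, index=list(self.labels)).sort_values(ascending=False)


def _linkage_to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as newick with ultrametric branch lengths.

    A node that merged at height h sits at depth h/2 from the tips, so the
    branch from its parent (merged at H) has length (H - h) / 2; leaves have
    height 0.  For two strains at distance d this gives ``(A:d/2,B:d/2);``.
    """
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes: dict[int, str] = {}

    def render(idx: int, parent_height: float) -> str:
        length = (parent_height - heights[idx]) / 2.0
        if idx < n:
            return f"{labels[idx]}:{length:.6f}"
        return f"{nodes[idx]}:{length:.6f}"

    for step, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        new = n + step
        heights[new] = float(h)
        nodes[new] = f"({render(a, float(h))},{render(b, float(h))})"
    root = n + len(z) - 1
    return nodes[root] + ";"


def splicing_phylogeny(
    matrix: SharingMatrix,
    method: Literal["average", "complete", "single"] = "average",
) -> Phylogeny:
    """Cluster strains by Euclidean distance between sharing-matrix rows.

    Strains are processed in lexicographic label order so that the result
    is invariant to input order (ties break deterministically).
    """
    shared = np.asarray(matrix.shared, dtype=float)
    if shared.shape[0] != shared.shape[1] or not np.allclose(shared, shared.T):
        raise ValueError("sharing matrix must be square and symmetric")
    if shared.shape[0] < 2:
        raise ValueError("phylogeny requires >= 2 strains")
    order = np.argsort(np.asarray(matrix.strains))
    labels = tuple(matrix.strains[i] for i in order)
    rows = shared[np.ix_(order, order)]
    z = linkage(pdist(rows, metric="euclidean"), method=method)
    return Phylogeny(labels, z, _linkage_to_newick(z, labels))
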