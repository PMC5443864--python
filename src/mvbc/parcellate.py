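"""Spatially constrained Ward agglomeration and median cluster features.

Each in-mask voxel is treated as an observation whose feature vector is its
value across the *training* subjects ("clustering in the space of
subjects").  Adjacent clusters are merged greedily by Ward's
minimum-variance criterion until the requested number of parcels remains;
only voxels adjacent under the chosen 3-D connectivity may merge, so every
parcel is spatially contiguous.  A fitted parcelation is then applied to
any subjects (including held-out ones) by taking, per parcel, the median of
the member voxels' values.
"""

from __future__ import annotations

import heapq
import json
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .data_model import BrainMask, ViewDataset, save_map, load_mask

__all__ = [
    "AdjacencyGraph",
    "WardTree",
    "Parcelation",
    "FeatureMatrix",
    "build_adjacency",
    "ward_linkage",
    "fit_parcelation",
    "extract_features",
    "save_parcelation",
    "load_parcelation",
]


def _offsets(connectivity: int) -> np.ndarray:
    """Positive-halfspace neighbour offsets for 6/18/26 connectivity."""
    if connectivity not in (6, 18, 26):
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) <= (0, 0, 0):
                    continue  # keep one direction per unordered pair
                m = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and m != 1:
                    continue
                if connectivity == 18 and m > 2:
                    continue
                offs.append((dx, dy, dz))
    return np.asarray(offs, dtype=np.intp)


@dataclass(frozen=True, eq=False)
class AdjacencyGraph:
    """Symmetric in-mask voxel adjacency as an (m, 2) edge array (a < b)."""

    n_voxels: int
    edges: np.ndarray
    connectivity: int = 6

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        if edges.size:
            if (edges[:, 0] == edges[:, 1]).any():
                raise ValueError("self-loops are not allowed")
            edges = np.sort(edges, axis=1)
            edges = np.unique(edges, axis=0)
            if edges.min() < 0 or edges.max() >= self.n_voxels:
                raise ValueError("edge endpoint out of range")
        edges.setflags(write=False)
        object.__setattr__(self, "edges", edges)

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def to_sparse(self) -> sp.csr_matrix:
        if self.n_edges == 0:
            return sp.csr_matrix((self.n_voxels, self.n_voxels))
        a, b = self.edges.T
        data = np.ones(2 * self.n_edges)
        return sp.csr_matrix(
            (data, (np.concatenate([a, b]), np.concatenate([b, a]))),
            shape=(self.n_voxels, self.n_voxels),
        )

    def neighbor_sets(self) -> list[set[int]]:
        nbrs: list[set[int]] = [set() for _ in range(self.n_voxels)]
        for a, b in self.edges:
            nbrs[a].add(int(b))
            nbrs[b].add(int(a))
        return nbrs

    def n_components(self) -> int:
        ncomp, _ = sp.csgraph.connected_components(self.to_sparse(), directed=False)
        return int(ncomp)


def build_adjacency(mask: BrainMask, connectivity: int = 6) -> AdjacencyGraph:
    """Adjacency between in-mask voxels under 6/18/26 3-D connectivity."""
    offs = _offsets(connectivity)
    idvol = np.full(mask.shape, -1, dtype=np.intp)
    idvol[tuple(mask.indices.T)] = np.arange(mask.n_voxels)
    edges = []
    for off in offs:
        nbr = mask.indices + off
        ok = ((nbr >= 0) & (nbr < np.asarray(mask.shape))).all(axis=1)
        src = np.arange(mask.n_voxels)[ok]
        dst = idvol[tuple(nbr[ok].T)]
        hit = dst >= 0
        edges.append(np.column_stack([src[hit], dst[hit]]))
    all_edges = (
        np.concatenate(edges) if edges else np.empty((0, 2), dtype=np.intp)
    )
    return AdjacencyGraph(mask.n_voxels, all_edges, connectivity)


@dataclass(frozen=True, eq=False)
class WardTree:
    """Fitted constrained-Ward merge sequence.

    ``merges`` lists ``(a, b, new_id, height)`` in merge order; leaves are
    ids ``0..n-1`` and merged clusters take ids ``n, n+1, ...``.  Cutting
    after the first ``n - k`` merges yields the k-parcel labeling, so the
    parcelations at successive k form a strict nesting.
    """

    n_voxels: int
    n_components: int
    merges: tuple[tuple[int, int, int, float], ...]

    def cut(self, k: int) -> np.ndarray:
        """Labels in 0..k-1 (relabelled by first-voxel order) at k clusters."""
        if k < self.n_components or k > self.n_voxels:
            raise ValueError(
                f"k must be in [{self.n_components}, {self.n_voxels}], got {k}"
            )
        n_apply = self.n_voxels - k
        parent = np.arange(self.n_voxels + n_apply, dtype=np.intp)

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b, new, _ in self.merges[:n_apply]:
            parent[find(a)] = new
            parent[find(b)] = new
        roots = np.fromiter(
            (find(v) for v in range(self.n_voxels)), dtype=np.intp,
            count=self.n_voxels,
        )
        _, labels = np.unique(roots, return_inverse=True)
        # relabel so cluster ids follow first occurrence in voxel order
        order = np.full(labels.max() + 1, -1, dtype=np.intp)
        nxt = 0
        for lab in labels:
            if order[lab] < 0:
                order[lab] = nxt
                nxt += 1
        return order[labels]


def ward_linkage(X: np.ndarray, adjacency: AdjacencyGraph) -> WardTree:
    """Greedy adjacency-constrained Ward agglomeration.

    ``X`` is voxels x features (features = training subjects).  The merge
    height between clusters A, B is the Ward variance increase
    ``|A||B| / (|A| + |B|) * ||mean_A - mean_B||^2``; ties break on the
    lexicographically lowest cluster-id pair.  Clusters in different
    connected components are never merged.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n != adjacency.n_voxels:
        raise ValueError("data rows must match adjacency voxel count")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in clustering data")
    size: dict[int, int] = {i: 1 for i in range(n)}
    cent: dict[int, np.ndarray] = {i: X[i] for i in range(n)}
    nbrs: dict[int, set[int]] = defaultdict(set)
    for a, b in adjacency.edges:
        nbrs[int(a)].add(int(b))
        nbrs[int(b)].add(int(a))

    def ward_d(a: int, b: int) -> float:
        sa, sb = size[a], size[b]
        diff = cent[a] - cent[b]
        return sa * sb / (sa + sb) * float(diff @ diff)

    heap: list[tuple[float, int, int]] = [
        (ward_d(int(a), int(b)), int(a), int(b)) for a, b in adjacency.edges
    ]
    heapq.heapify(heap)
    active = set(range(n))
    merges: list[tuple[int, int, int, float]] = []
    next_id = n
    while heap:
        d, a, b = heapq.heappop(heap)
        if a not in active or b not in active or b not in nbrs[a]:
            continue  # stale entry
        new = next_id
        next_id += 1
        merges.append((a, b, new, d))
        sa, sb = size[a], size[b]
        size[new] = sa + sb
        cent[new] = (sa * cent[a] + sb * cent[b]) / (sa + sb)
        new_nbrs = (nbrs[a] | nbrs[b]) - {a, b}
        nbrs[new] = new_nbrs
        for c in new_nbrs:
            nbrs[c].discard(a)
            nbrs[c].discard(b)
            nbrs[c].add(new)
            heapq.heappush(heap, (ward_d(c, new), min(c, new), max(c, new)))
        active.discard(a)
        active.discard(b)
        active.add(new)
        del size[a], size[b], cent[a], cent[b], nbrs[a], nbrs[b]
    return WardTree(n, n - len(merges), tuple(merges))


@dataclass(frozen=True, eq=False)
class Parcelation:
    """Voxel -> parcel labeling fitted on training subjects only."""

    view_name: str
    labels: np.ndarray
    k: int
    fit_subjects: tuple[str, ...]
    connectivity: int = 6

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.intp)
        uniq = np.unique(labels)
        if not np.array_equal(uniq, np.arange(self.k)):
            raise ValueError("labels must cover 0..k-1 contiguously")
        labels.setflags(write=False)
        object.__setattr__(self, "labels", labels)

    @property
    def n_voxels(self) -> int:
        return int(self.labels.shape[0])

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    def cluster_members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)


def fit_parcelation(
    view: ViewDataset,
    adjacency: AdjacencyGraph,
    k: int,
    tree: WardTree | None = None,
) -> Parcelation:
    """Fit a k-parcel constrained-Ward parcelation on a training view.

    The view should already be restricted to training subjects (and, if
    desired, confound-residualized).  A precomputed :func:`ward_linkage`
    tree for the same view/adjacency may be passed to reuse the linkage
    across several values of k.
    """
    if view.mask.n_voxels != adjacency.n_voxels:
        raise ValueError("adjacency does not match view mask")
    if tree is None:
        tree = ward_linkage(view.data.T, adjacency)
    labels = tree.cut(k)
    return Parcelation(
        view.view_name, labels, k, view.subject_ids, adjacency.connectivity
    )


@dataclass(frozen=True, eq=False)
class FeatureMatrix:
    """Subjects x features matrix with stable, view-traceable column names."""

    data: np.ndarray
    feature_names: tuple[str, ...]
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        names = tuple(self.feature_names)
        ids = tuple(self.subject_ids)
        if data.ndim != 2 or data.shape != (len(ids), len(names)):
            raise ValueError("feature matrix shape does not match names/subjects")
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if not np.isfinite(data).all():
            raise ValueError("non-finite feature values")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "feature_names", names)
        object.__setattr__(self, "subject_ids", ids)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def restrict(self, rows: Sequence[int]) -> "FeatureMatrix":
        rows = np.asarray(rows, dtype=int)
        return FeatureMatrix(
            self.data[rows],
            self.feature_names,
            tuple(self.subject_ids[i] for i in rows),
        )


def extract_features(
    view: ViewDataset, parcelation: Parcelation, aggregator: str = "median"
) -> FeatureMatrix:
    """Aggregate each parcel's voxel values per subject (median by default).

    Applicable to any subjects measured on the parcelation's mask geometry,
    in particular held-out subjects with a training-fit parcelation.  The
    mean aggregator exists for ablation only.
    """
    if view.mask.n_voxels != parcelation.n_voxels:
        raise ValueError("view geometry does not match parcelation")
    if aggregator not in ("median", "mean"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    agg = np.median if aggregator == "median" else np.mean
    out = np.empty((view.n_subjects, parcelation.k))
    for c in range(parcelation.k):
        out[:, c] = agg(view.data[:, parcelation.labels == c], axis=1)
    names = tuple(
        f"{parcelation.view_name}:c{c:04d}" for c in range(parcelation.k)
    )
    return FeatureMatrix(out, names, view.subject_ids)


def save_parcelation(
    parcelation: Parcelation, mask: BrainMask, stem: str | Path
) -> tuple[Path, Path]:
    """Write a parcelation as NIfTI labels (+1; 0 = out of mask) + JSON."""
    stem = Path(stem)
    nii = stem.with_suffix(".nii.gz")
    meta = stem.with_suffix(".json")
    save_map(parcelation.labels + 1.0, mask, nii)
    meta.write_text(
        json.dumps(
            {
                "view_name": parcelation.view_name,
                "k": parcelation.k,
                "connectivity": parcelation.connectivity,
                "fit_subjects": list(parcelation.fit_subjects),
            },
            indent=2,
        )
    )
    return nii, meta


def load_parcelation(stem: str | Path) -> tuple[Parcelation, BrainMask]:
    stem = Path(stem)
    import nibabel as nib

    img = nib.load(str(stem.with_suffix(".nii.gz")))
    vol = np.asanyarray(img.dataobj)
    mask = BrainMask.from_volume(vol > 0, img.affine)
    labels = np.rint(mask.extract(np.asarray(vol, dtype=float))).astype(int) - 1
    meta = json.loads(stem.with_suffix(".json").read_text())
    parc = Parcelation(
        meta["view_name"],
        labels,
        int(meta["k"]),
        tuple(meta["fit_subjects"]),
        int(meta["connectivity"]),
    )
    return parc, mask
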