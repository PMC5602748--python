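"""Electrode localization: metal segmentation in CT-like volumes and
nearest-vertex snapping onto the cortical mesh.

Subdural platinum electrodes are radio-opaque: brain tissue images at 20–120
Hounsfield units while metal exceeds 3000 HU, so a plain threshold isolates
the contacts. Each 26-connected component's centroid (mean of voxel centers
mapped through the volume affine) stands in for the contact position, and is
snapped to the closest cortical-mesh vertex by Euclidean distance. CT–MRI
co-registration is an input contract: affines are assumed already aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateSnapError
from .mesh import TriMesh

__all__ = ["Volume3D", "MetalComponent", "ElectrodeSet", "segment_metal",
           "snap_to_mesh", "order_collinear"]


@dataclass
class Volume3D:
    """A 3-D intensity volume (HU) with a voxel→world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine not invertible")
        if (self.voxel_size <= 0).any():
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    @classmethod
    def from_nifti(cls, path: str) -> "Volume3D":
        import nibabel as nib

        img = nib.load(path)
        return cls(np.asarray(img.dataobj), img.affine)

    def to_nifti(self, path: str) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32),
                                 self.affine), path)


@dataclass
class MetalComponent:
    """One 26-connected supra-threshold component."""

    voxels: np.ndarray          # (k, 3) integer voxel indices
    centroid: np.ndarray        # (3,) world mm

    @property
    def size(self) -> int:
        return len(self.voxels)


def segment_metal(volume: Volume3D, threshold: float = 3000.0) -> list[MetalComponent]:
    """26-connected components of voxels above ``threshold`` HU.

    Returns one :class:`MetalComponent` per component with its world-space
    centroid. An empty volume yields an empty list and a warning, never an
    exception (missing electrodes are a data problem, not a programming one).
    """
    mask = volume.data > threshold
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        warnings.warn("no voxels above threshold; no metal components found")
        return []
    out = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        centroid = volume.voxel_to_world(vox.astype(np.float64)).mean(axis=0)
        out.append(MetalComponent(voxels=vox, centroid=centroid))
    return out


@dataclass
class ElectrodeSet:
    """Ordered electrode contacts: labels E1..En along the strip, world
    centroids, snapped mesh vertex ids and snap distances."""

    labels: list[str]
    centroids: np.ndarray
    vertex_ids: np.ndarray
    snap_distances: np.ndarray = field(default=None)
    spacing: float = 10.0
    order_inferred: bool = False

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=np.float64).reshape(-1, 3)
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=np.int64)
        if self.snap_distances is None:
            self.snap_distances = np.full(len(self.labels), np.nan)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if len(set(self.vertex_ids.tolist())) != len(self.vertex_ids):
            raise DegenerateSnapError(
                "degenerate snap: two electrodes share one mesh vertex"
            )

    def as_dict(self) -> dict[str, int]:
        return {lab: int(v) for lab, v in zip(self.labels, self.vertex_ids)}

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {
                "label": self.labels,
                "x_mm": self.centroids[:, 0],
                "y_mm": self.centroids[:, 1],
                "z_mm": self.centroids[:, 2],
                "vertex_id": self.vertex_ids,
                "snap_distance_mm": self.snap_distances,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, spacing: float = 10.0) -> "ElectrodeSet":
        df = pd.read_csv(path)
        return cls(
            labels=df["label"].astype(str).tolist(),
            centroids=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
            vertex_ids=df["vertex_id"].to_numpy(),
            snap_distances=df["snap_distance_mm"].to_numpy()
            if "snap_distance_mm" in df
            else None,
            spacing=spacing,
        )


def order_collinear(centroids: np.ndarray) -> np.ndarray:
    """Order centroids along their principal axis (for a collinear strip).

    Returns the permutation; orientation is fixed so the first contact is the
    one with the lexicographically smallest coordinate tuple of the two ends.
    """
    c = np.asarray(centroids, dtype=np.float64)
    center = c - c.mean(axis=0)
    _, _, vt = np.linalg.svd(center, full_matrices=False)
    proj = center @ vt[0]
    order = np.argsort(proj)
    first, last = c[order[0]], c[order[-1]]
    if tuple(last) < tuple(first):
        order = order[::-1]
    return order


def snap_to_mesh(
    centroids: np.ndarray,
    mesh: TriMesh,
    labels: list[str] | None = None,
    infer_order: bool = False,
    spacing: float = 10.0,
) -> ElectrodeSet:
    """Map each centroid to the nearest mesh vertex (Euclidean; ties broken
    toward the smallest vertex id).

    With ``infer_order=True`` the contacts are first sorted along the strip's
    principal axis (labels then follow that order); otherwise the given order
    is kept. Two centroids snapping to one vertex raise
    :class:`DegenerateSnapError`.
    """
    centroids = np.asarray(centroids, dtype=np.float64).reshape(-1, 3)
    if mesh.n_vertices == 0:
        raise ValueError("empty mesh")
    order_inferred = False
    if infer_order:
        perm = order_collinear(centroids)
        centroids = centroids[perm]
        order_inferred = True
    if labels is None:
        labels = [f"E{i + 1}" for i in range(len(centroids))]

    vids = np.empty(len(centroids), dtype=np.int64)
    dists = np.empty(len(centroids))
    for i, c in enumerate(centroids):
        d = np.linalg.norm(mesh.vertices - c, axis=1)
        vids[i] = int(np.argmin(d))      # argmin returns the smallest index on ties
        dists[i] = d[vids[i]]
    return ElectrodeSet(
        labels=list(labels),
        centroids=centroids,
        vertex_ids=vids,
        snap_distances=dists,
        spacing=spacing,
        order_inferred=order_inferred,
    )
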