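"""Triangulated cortical surface meshes.

All downstream metrics (2dReHo neighborhoods, smoothing, cluster
formation) are defined on a single triangulated mesh shared by every
subject, in the spirit of FreeSurfer's fsaverage templates.  Vertices are
0-based throughout.  The medial wall and other non-analyzable regions are
carried as a boolean ``cortex_mask``; masked vertices are excluded from
every statistic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc

__all__ = [
    "SurfaceMesh",
    "load_surface",
    "save_gifti_surface",
    "make_icosphere",
    "one_ring_neighbors",
    "connected_components",
    "average_edge_length",
]


@dataclass
class SurfaceMesh:
    """A shared triangulated cortical sheet.

    Parameters
    ----------
    vertex_coords : (V, 3) float array
        Vertex positions in mm.
    triangles : (F, 3) int array
        Vertex-index triples; each triple must reference three distinct
        valid vertices.
    cortex_mask : (V,) bool array, optional
        True where a vertex is analyzable cortex.  Defaults to all-true;
        vertices belonging to no triangle are always masked out.
    """

    vertex_coords: np.ndarray
    triangles: np.ndarray
    cortex_mask: np.ndarray | None = None
    _adjacency: sp.csr_matrix | None = field(default=None, repr=False, compare=False)
    _neighbor_lists: list | None = field(default=None, repr=False, compare=False)
    _vertex_areas: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertex_coords.ndim != 2 or self.vertex_coords.shape[1] != 3:
            raise ValueError("vertex_coords must be (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (F, 3)")
        V = self.n_vertices
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= V:
                raise ValueError("triangle index out of range")
            degenerate = (
                (self.triangles[:, 0] == self.triangles[:, 1])
                | (self.triangles[:, 1] == self.triangles[:, 2])
                | (self.triangles[:, 0] == self.triangles[:, 2])
            )
            if degenerate.any():
                raise ValueError("triangle with repeated vertex index")
        if self.cortex_mask is None:
            self.cortex_mask = np.ones(V, dtype=bool)
        else:
            self.cortex_mask = np.asarray(self.cortex_mask, dtype=bool).copy()
            if self.cortex_mask.shape != (V,):
                raise ValueError("mask length mismatch")
        # Vertices that belong to no triangle cannot participate in any
        # neighborhood statistic; mask them out unconditionally.
        used = np.zeros(V, dtype=bool)
        used[self.triangles.ravel()] = True
        self.cortex_mask &= used
        if not self.cortex_mask.any():
            raise ValueError("cortex_mask has no true entries")

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric boolean vertex adjacency derived from triangle edges."""
        if self._adjacency is None:
            t = self.triangles
            rows = np.concatenate([t[:, 0], t[:, 1], t[:, 2], t[:, 1], t[:, 2], t[:, 0]])
            cols = np.concatenate([t[:, 1], t[:, 2], t[:, 0], t[:, 0], t[:, 1], t[:, 2]])
            data = np.ones(rows.size, dtype=np.int8)
            A = sp.coo_matrix((data, (rows, cols)), shape=(self.n_vertices,) * 2)
            A = A.tocsr()
            A.data[:] = 1
            self._adjacency = A
        return self._adjacency

    @property
    def neighbor_lists(self) -> list[np.ndarray]:
        """Per-vertex sorted arrays of 1-ring neighbor indices."""
        if self._neighbor_lists is None:
            A = self.adjacency
            self._neighbor_lists = [
                A.indices[A.indptr[i] : A.indptr[i + 1]].copy()
                for i in range(self.n_vertices)
            ]
        return self._neighbor_lists

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array with e[:,0] < e[:,1]."""
        A = sp.triu(self.adjacency, k=1).tocoo()
        return np.column_stack([A.row, A.col])

    @property
    def vertex_areas(self) -> np.ndarray:
        """Per-vertex area (mm^2): one third of each incident triangle.

        A barycentric approximation to Voronoi areas; positive at every
        triangle-member vertex and summing exactly to the total mesh area.
        """
        if self._vertex_areas is None:
            p = self.vertex_coords
            t = self.triangles
            cross = np.cross(p[t[:, 1]] - p[t[:, 0]], p[t[:, 2]] - p[t[:, 0]])
            tri_area = 0.5 * np.linalg.norm(cross, axis=1)
            areas = np.zeros(self.n_vertices)
            for k in range(3):
                np.add.at(areas, t[:, k], tri_area / 3.0)
            self._vertex_areas = areas
        return self._vertex_areas

    def total_area(self, masked_only: bool = False) -> float:
        a = self.vertex_areas
        return float(a[self.cortex_mask].sum() if masked_only else a.sum())


# ---------------------------------------------------------------------------
# I/O

def _read_mask(mask_path: str, n_vertices: int) -> np.ndarray:
    import nibabel as nib

    if mask_path.endswith(".gii"):
        img = nib.load(mask_path)
        data = img.darrays[0].data
        if data.shape[0] != n_vertices:
            raise ValueError("mask length mismatch")
        return np.asarray(data != 0)
    # FreeSurfer label: listed vertices belong to cortex
    idx = nib.freesurfer.read_label(mask_path)
    if idx.size and idx.max() >= n_vertices:
        raise ValueError("mask label index out of range")
    mask = np.zeros(n_vertices, dtype=bool)
    mask[idx] = True
    return mask


def load_surface(geometry_path: str, mask_path: str | None = None) -> SurfaceMesh:
    """Load a surface from GIFTI (.gii) or FreeSurfer binary geometry.

    The optional mask may be a GIFTI label/scalar file (nonzero = cortex)
    or a FreeSurfer label file (listed vertices = cortex).
    """
    import nibabel as nib

    if not os.path.exists(geometry_path):
        raise FileNotFoundError(geometry_path)
    if geometry_path.endswith(".gii"):
        img = nib.load(geometry_path)
        coords = tris = None
        for da in img.darrays:
            intent = da.intent
            if intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                coords = np.asarray(da.data, dtype=np.float64)
            elif intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                tris = np.asarray(da.data, dtype=np.int64)
        if coords is None or tris is None:
            raise ValueError(f"{geometry_path}: no POINTSET/TRIANGLE arrays")
    else:
        coords, tris = nib.freesurfer.read_geometry(geometry_path)
        coords = np.asarray(coords, dtype=np.float64)
        tris = np.asarray(tris, dtype=np.int64)
    mask = _read_mask(mask_path, coords.shape[0]) if mask_path else None
    return SurfaceMesh(coords, tris, mask)


def save_gifti_surface(mesh: SurfaceMesh, path: str) -> None:
    """Write mesh geometry to a GIFTI .surf.gii file."""
    import nibabel as nib
    from nibabel.gifti import GiftiDataArray, GiftiImage

    da_pts = GiftiDataArray(
        mesh.vertex_coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    da_tri = GiftiDataArray(
        mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    nib.save(GiftiImage(darrays=[da_pts, da_tri]), path)


# ---------------------------------------------------------------------------
# Icosphere fixtures

_PHI = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array(
    [
        [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
        [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
        [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
    ],
    dtype=np.float64,
)

_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def make_icosphere(subdivision_level: int, radius: float = 1.0) -> SurfaceMesh:
    """Subdivided icosahedron projected onto a sphere of given radius (mm).

    Vertex count follows 10*4^level + 2 (level 7 gives the 163,842 of
    fsaverage; level 5 the 10,242 of an fsaverage5 hemisphere).
    """
    if subdivision_level < 0:
        raise ValueError("subdivision_level must be >= 0")
    if subdivision_level > 7:
        raise ValueError("subdivision_level > 7 refused (resource guard)")
    verts = [v for v in _ICO_VERTS]
    faces = _ICO_FACES
    for _ in range(subdivision_level):
        midpoint: dict[tuple[int, int], int] = {}
        new_faces = []

        def mid(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in midpoint:
                verts.append(0.5 * (verts[a] + verts[b]))
                midpoint[key] = len(verts) - 1
            return midpoint[key]

        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        faces = np.asarray(new_faces, dtype=np.int64)
    coords = np.asarray(verts)
    coords = radius * coords / np.linalg.norm(coords, axis=1, keepdims=True)
    return SurfaceMesh(coords, faces)


# ---------------------------------------------------------------------------
# Queries

def one_ring_neighbors(
    mesh: SurfaceMesh, vertex_index: int, respect_mask: bool = False
) -> set[int]:
    """Vertices sharing a triangle edge with ``vertex_index`` (itself excluded).

    With ``respect_mask`` the result is restricted to cortex vertices.
    """
    if not 0 <= vertex_index < mesh.n_vertices:
        raise IndexError(f"vertex index {vertex_index} out of range")
    nbrs = mesh.neighbor_lists[vertex_index]
    if respect_mask:
        nbrs = nbrs[mesh.cortex_mask[nbrs]]
    return set(int(i) for i in nbrs)


def connected_components(mesh: SurfaceMesh, vertex_mask: np.ndarray) -> list[np.ndarray]:
    """Maximal edge-connected sets of true vertices.

    Components are sorted by descending size, ties broken by smallest
    contained vertex index.  An all-false mask yields an empty list.
    """
    vertex_mask = np.asarray(vertex_mask, dtype=bool)
    if vertex_mask.shape != (mesh.n_vertices,):
        raise ValueError("vertex_mask length mismatch")
    idx = np.flatnonzero(vertex_mask)
    if idx.size == 0:
        return []
    sub = mesh.adjacency[np.ix_(idx, idx)]
    n_comp, labels = _cc(sub, directed=False)
    comps = [idx[labels == k] for k in range(n_comp)]
    comps.sort(key=lambda c: (-c.size, c.min()))
    return comps


def average_edge_length(mesh: SurfaceMesh) -> float:
    """Arithmetic mean of unique-edge Euclidean lengths (mm)."""
    e = mesh.edges
    if e.shape[0] == 0:
        raise ValueError("mesh has no edges")
    d = np.linalg.norm(mesh.vertex_coords[e[:, 0]] - mesh.vertex_coords[e[:, 1]], axis=1)
    return float(d.mean())
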