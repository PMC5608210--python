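"""Air-to-tissue interface curvature: normal-cycle estimation and ISD plots.

Pipeline: marching-cubes surface extraction from the binary segmentation,
umbrella-operator Laplacian smoothing, then a normal-cycle curvature tensor
per vertex.  For a vertex v the tensor accumulates, over every mesh edge e
intersecting the geodesic ball B(v, R),

    T(v) = (1/area(B)) Σ_e  β(e) · ℓ(e ∩ B) · ē ēᵀ,

with β(e) the signed dihedral angle at e (positive at edges convex with
respect to the outward normals) and ē the unit edge direction.  The two
tangent-plane eigenvalues of T are the principal curvatures κ1 ≤ κ2 (the
normal-cycle tensor carries the eigenvalues on swapped eigendirections,
which leaves the unordered value pair unchanged); H = (κ1 + κ2)/2 and
K = κ1 κ2 follow, consistent with κ_{1,2} = H ∓ √(H² − K).

Surface normals are oriented from the air volume toward the tissue, so an
air cavity (alveolus surrogate) has κ1, κ2 > 0.  Vertices whose geodesic
ball is truncated by a mesh boundary are flagged and excluded from all
densities.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import trimesh
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from skimage import measure

from .density import DensityEstimate, ISDensity, kde_1d, kde_2d
from .volio import BinaryVolume

logger = logging.getLogger("lungmorph")

#: Geodesic-radius presets, µm (interpreted in the mesh's native length unit).
GEODESIC_RADIUS_FINE = 3.5
GEODESIC_RADIUS_COARSE = 15.0

REGION_EXCLUDED = 0  # boundary-truncated neighborhood


@dataclasses.dataclass
class SurfaceMesh:
    """Triangulated air-to-tissue interface in physical µm coordinates."""

    vertices: np.ndarray
    triangles: np.ndarray
    vertex_normals: np.ndarray
    spacing: float
    source_mask: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangles index non-existent vertices")
        norms = np.linalg.norm(self.vertex_normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            self.vertex_normals = self.vertex_normals / norms[:, None]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)


@dataclasses.dataclass
class CurvatureField:
    """Per-vertex principal/mean/Gaussian curvatures with region labels."""

    kappa1: np.ndarray  # µm^-1, kappa1 <= kappa2
    kappa2: np.ndarray
    H: np.ndarray  # µm^-1
    K: np.ndarray  # µm^-2
    geodesic_radius: float
    excluded: np.ndarray  # True where the geodesic ball was boundary-truncated
    region: np.ndarray | None = None

    @property
    def included(self) -> np.ndarray:
        return ~self.excluded


def extract_surface(mask: BinaryVolume) -> SurfaceMesh:
    """Marching-cubes iso-surface of the air phase at level 0.5.

    Vertices are physical (z, y, x) µm coordinates; normals are oriented
    from air into tissue; triangles are wound consistently with them.
    """
    air = (~mask.data).astype(np.float32)
    if air.min() == air.max():
        raise ValueError("mask has a single phase; no interface to extract")
    s = mask.spacing
    verts, faces, _, _ = measure.marching_cubes(air, level=0.5, spacing=(s, s, s))
    tm = trimesh.Trimesh(verts, faces, process=False)
    normals = np.asarray(tm.vertex_normals, dtype=float)
    # Orientation check: stepping along the normal must leave the air phase.
    probe = (verts + 0.75 * s * normals) / s
    ahead = ndimage.map_coordinates(air, probe.T, order=1, mode="nearest")
    behind = ndimage.map_coordinates(air, ((verts - 0.75 * s * normals) / s).T, order=1, mode="nearest")
    if np.mean(ahead - behind) > 0:  # normals currently point into the air: flip
        faces = faces[:, ::-1]
        tm = trimesh.Trimesh(verts, faces, process=False)
        normals = np.asarray(tm.vertex_normals, dtype=float)
    return SurfaceMesh(verts, faces, normals, s, {"tissue_fraction": mask.tissue_fraction, **mask.meta})


def smooth_mesh(mesh: SurfaceMesh, iterations: int = 20, step: float = 0.5) -> SurfaceMesh:
    """Umbrella-operator Laplacian smoothing (connectivity unchanged).

    Each iteration moves every vertex by ``step`` times the difference
    between its one-ring average and itself; iterations=0 is the identity.
    Plain umbrella smoothing shrinks enclosed volume slightly; the shrinkage
    is logged.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not 0 < step < 1:
        raise ValueError("step must lie in (0, 1)")
    if iterations == 0:
        return SurfaceMesh(mesh.vertices.copy(), mesh.triangles.copy(), mesh.vertex_normals.copy(), mesh.spacing, dict(mesh.source_mask))
    tm = mesh.to_trimesh()
    edges = tm.edges_unique
    n = mesh.n_vertices
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1
    verts = mesh.vertices.copy()
    vol_before = abs(tm.volume) if tm.is_watertight else None
    for _ in range(iterations):
        verts += step * (adj @ verts / deg[:, None] - verts)
    out_tm = trimesh.Trimesh(verts, mesh.triangles, process=False)
    if vol_before:
        shrink = 1.0 - abs(out_tm.volume) / vol_before
        logger.info("smooth_mesh: %d iterations, enclosed volume shrank by %.2f%%", iterations, 100 * shrink)
    return SurfaceMesh(verts, mesh.triangles.copy(), np.asarray(out_tm.vertex_normals, dtype=float), mesh.spacing, dict(mesh.source_mask))


def _signed_dihedral(tm: trimesh.Trimesh) -> tuple[np.ndarray, np.ndarray]:
    """(edge vertex pairs, signed dihedral angles) over interior edges.

    Positive where the edge is convex with respect to the face normals
    (normals diverge), negative where concave.
    """
    pairs = tm.face_adjacency  # (n_e, 2) face indices sharing an edge
    edges = tm.face_adjacency_edges  # (n_e, 2) vertex indices
    n1 = tm.face_normals[pairs[:, 0]]
    n2 = tm.face_normals[pairs[:, 1]]
    cosang = np.clip((n1 * n2).sum(axis=1), -1.0, 1.0)
    angles = np.arccos(cosang)
    # convexity: the hinge opens away from the normals — test whether the
    # opposite vertex of face 2 lies behind face 1's plane
    opposite = tm.face_adjacency_unshared[:, 1]
    v_opp = tm.vertices[opposite]
    on_edge = tm.vertices[edges[:, 0]]
    convex = ((v_opp - on_edge) * n1).sum(axis=1) < 0
    return edges, np.where(convex, angles, -angles)


def normal_cycle_curvature(mesh: SurfaceMesh, geodesic_radius: float, chunk: int = 96) -> CurvatureField:
    """Normal-cycle curvature tensor per vertex over geodesic neighborhoods.

    Geodesic balls are grown by Dijkstra over the edge graph with Euclidean
    edge weights; the accumulated edge tensor is normalised by the
    barycentric area of the reached vertices; the tangent-plane eigenvalues
    give κ1 ≤ κ2.  Vertices whose ball touches a mesh boundary are labeled
    boundary-excluded.
    """
    if geodesic_radius <= 0:
        raise ValueError("geodesic_radius must be > 0")
    tm = mesh.to_trimesh()
    n = mesh.n_vertices
    edges_all = tm.edges_unique
    lens_all = tm.edges_unique_length
    if lens_all.min() > geodesic_radius:
        raise ValueError("geodesic_radius is smaller than every edge length; neighborhoods are empty")
    graph = coo_matrix(
        (np.concatenate([lens_all, lens_all]),
         (np.concatenate([edges_all[:, 0], edges_all[:, 1]]), np.concatenate([edges_all[:, 1], edges_all[:, 0]]))),
        shape=(n, n),
    ).tocsr()

    int_edges, beta = _signed_dihedral(tm)
    evec = mesh.vertices[int_edges[:, 1]] - mesh.vertices[int_edges[:, 0]]
    elen = np.linalg.norm(evec, axis=1)
    elen[elen == 0] = 1e-12
    ehat = evec / elen[:, None]
    # symmetric outer products as 6 components (zz, yy, xx, zy, zx, yx)
    outer6 = np.column_stack([
        ehat[:, 0] ** 2, ehat[:, 1] ** 2, ehat[:, 2] ** 2,
        ehat[:, 0] * ehat[:, 1], ehat[:, 0] * ehat[:, 2], ehat[:, 1] * ehat[:, 2],
    ])
    edge_tensor6 = (beta * elen)[:, None] * outer6  # full-edge contribution

    # boundary vertices: on edges referenced by exactly one face
    counts = np.zeros(len(edges_all), dtype=np.int64)
    np.add.at(counts, tm.edges_unique_inverse, 1)
    is_boundary = np.zeros(n, dtype=bool)
    is_boundary[edges_all[counts == 1].ravel()] = True

    vertex_area = np.zeros(n)
    np.add.at(vertex_area, tm.faces.ravel(), np.repeat(tm.area_faces / 3.0, 3))

    # incidence of interior edges on vertices, for chunk-local edge sets
    ne = len(int_edges)
    incidence = coo_matrix(
        (np.ones(2 * ne), (np.concatenate([int_edges[:, 0], int_edges[:, 1]]), np.tile(np.arange(ne), 2))),
        shape=(n, ne),
    ).tocsr()

    # Geodesic balls are contained in Euclidean balls of the same radius, so
    # each chunk of sources only needs Dijkstra on the subgraph of vertices
    # within Euclidean distance R of some source.
    tree = cKDTree(mesh.vertices)
    glob2loc = np.full(n, -1, dtype=np.int64)
    tensors = np.zeros((n, 6))
    areas = np.zeros(n)
    excluded = np.zeros(n, dtype=bool)
    for start in range(0, n, chunk):
        idx = np.arange(start, min(start + chunk, n))
        balls = tree.query_ball_point(mesh.vertices[idx], geodesic_radius * (1 + 1e-9))
        cand = np.unique(np.concatenate([np.asarray(b, dtype=np.int64) for b in balls]))
        glob2loc[cand] = np.arange(cand.size)
        sub = graph[cand][:, cand]
        dmat = dijkstra(sub, directed=False, indices=glob2loc[idx], limit=geodesic_radius)
        reached = np.isfinite(dmat)
        local_edges = np.unique(incidence[cand].indices)
        if local_edges.size == 0:
            excluded[idx] = True
            glob2loc[cand] = -1
            continue
        ea = glob2loc[int_edges[local_edges, 0]]
        eb = glob2loc[int_edges[local_edges, 1]]
        da = dmat[:, np.clip(ea, 0, cand.size - 1)]
        db = dmat[:, np.clip(eb, 0, cand.size - 1)]
        da[:, ea < 0] = np.inf  # endpoint outside every source's Euclidean ball
        db[:, eb < 0] = np.inf
        both = np.isfinite(da) & np.isfinite(db)
        dmin = np.minimum(np.where(np.isfinite(da), da, np.inf), np.where(np.isfinite(db), db, np.inf))
        partial = np.clip((geodesic_radius - dmin) / elen[local_edges][None, :], 0.0, 1.0)
        w = np.where(both, 1.0, partial)
        tensors[idx] = w @ edge_tensor6[local_edges]
        areas[idx] = reached @ vertex_area[cand]
        # exclude truncated balls and degenerate neighborhoods (marching
        # cubes produces sliver vertices whose ball holds almost no area;
        # the area-normalised tensor is meaningless there)
        degenerate = (reached.sum(axis=1) < 4) | (areas[idx] < 1e-3 * np.pi * geodesic_radius**2)
        excluded[idx] = (reached @ is_boundary[cand] > 0) | degenerate
        glob2loc[cand] = -1

    areas[areas == 0] = np.inf
    t6 = tensors / areas[:, None]
    tmat = np.empty((n, 3, 3))
    tmat[:, 0, 0] = t6[:, 0]
    tmat[:, 1, 1] = t6[:, 1]
    tmat[:, 2, 2] = t6[:, 2]
    tmat[:, 0, 1] = tmat[:, 1, 0] = t6[:, 3]
    tmat[:, 0, 2] = tmat[:, 2, 0] = t6[:, 4]
    tmat[:, 1, 2] = tmat[:, 2, 1] = t6[:, 5]

    # project onto the tangent plane and take the two tangent eigenvalues
    nrm = mesh.vertex_normals
    proj = np.eye(3)[None] - nrm[:, :, None] * nrm[:, None, :]
    tt = proj @ tmat @ proj
    evals, evecs = np.linalg.eigh(tt)
    align = np.abs(np.einsum("nij,nj->ni", evecs.transpose(0, 2, 1), nrm))  # |eigvec · normal|
    normal_idx = np.argmax(align, axis=1)
    keep = np.ones((n, 3), dtype=bool)
    keep[np.arange(n), normal_idx] = False
    tangent_vals = evals[keep].reshape(n, 2)
    kappa1 = tangent_vals.min(axis=1)
    kappa2 = tangent_vals.max(axis=1)
    h = (kappa1 + kappa2) / 2.0
    k = kappa1 * kappa2
    return CurvatureField(kappa1, kappa2, h, k, geodesic_radius, excluded)


def principal_from_HK(H: np.ndarray | float, K: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """κ1 = H − √(H² − K), κ2 = H + √(H² − K); κ1 ≤ κ2.

    Negative discriminants (possible when H and K are estimated
    independently) are clamped to zero; clamp events are logged.
    """
    h = np.asarray(H, dtype=float)
    k = np.asarray(K, dtype=float)
    disc = h**2 - k
    n_clamped = int(np.sum(disc < 0))
    if n_clamped:
        logger.info("principal_from_HK: clamped %d negative discriminants", n_clamped)
    s = np.sqrt(np.clip(disc, 0.0, None))
    return h - s, h + s


def classify_regions(field: CurvatureField) -> np.ndarray:
    """ISD region labels per vertex (stored on the field and returned).

    Region 1: κ1, κ2 > 0 (ellipsoidal, convex toward tissue — alveolus-like);
    region 4: κ1, κ2 < 0 (concave); saddles κ1 < 0 < κ2 split into region 2
    (|κ1| ≥ κ2, ties to 2) and region 3 (|κ1| < κ2).  Exact zeros join the
    adjacent non-saddle region; boundary-excluded vertices get label 0.
    """
    k1, k2 = field.kappa1, field.kappa2
    labels = np.zeros(k1.shape, dtype=np.int8)
    labels[(k1 >= 0) & (k2 >= 0)] = 1
    labels[(k1 <= 0) & (k2 <= 0)] = 4
    labels[(k1 >= 0) & (k2 >= 0) & (k1 <= 0) & (k2 <= 0)] = 1  # the flat point κ1 = κ2 = 0
    saddle = (k1 < 0) & (k2 > 0)
    labels[saddle & (np.abs(k1) >= k2)] = 2
    labels[saddle & (np.abs(k1) < k2)] = 3
    labels[field.excluded] = REGION_EXCLUDED
    field.region = labels
    return labels


def _robust_grid(samples: np.ndarray, n_grid: int, q: float = 0.5) -> np.ndarray:
    """Evaluation grid spanning the [q, 100-q] percentile range, 10% padded.

    Marching-cubes meshes carry a small tail of extreme curvature outliers
    at single-voxel features; an unclipped grid would let them dominate the
    density's support.
    """
    lo, hi = np.percentile(samples, [q, 100 - q])
    pad = 0.1 * (hi - lo + 1e-12)
    return np.linspace(lo - pad, hi + pad, n_grid)


def isd_density(
    field: CurvatureField,
    grid_k1: np.ndarray | None = None,
    grid_k2: np.ndarray | None = None,
    n_grid: int = 256,
) -> ISDensity:
    """Interface shape distribution: 2D KDE over (κ1, κ2) of included vertices.

    The density is zeroed above the κ1 = κ2 diagonal (impossible by the
    ordering) and renormalised to unit mass.
    """
    inc = field.included
    k1 = field.kappa1[inc]
    k2 = field.kappa2[inc]
    if k1.size < 100:
        raise ValueError(f"too few included vertices for an ISD ({k1.size} < 100)")
    if grid_k1 is None:
        grid_k1 = _robust_grid(k1, n_grid)
    if grid_k2 is None:
        grid_k2 = _robust_grid(k2, n_grid)
    g1, g2, dens, bw = kde_2d(k1, k2, grid_k1, grid_k2, n_grid=n_grid)
    above = g1[:, None] > g2[None, :]  # κ1 > κ2: impossible half-plane
    dens = np.where(above, 0.0, dens)
    area = np.trapezoid(np.trapezoid(dens, g2, axis=1), g1)
    return ISDensity(g1, g2, dens / area, bw, int(k1.size))


def curvature_densities(
    field: CurvatureField,
    grid_H: np.ndarray | None = None,
    grid_K: np.ndarray | None = None,
) -> tuple[DensityEstimate, DensityEstimate]:
    """1D KDEs of mean curvature H (µm⁻¹) and Gaussian curvature K (µm⁻²)."""
    inc = field.included
    h = field.H[inc]
    k = field.K[inc]
    if h.size == 0:
        raise ValueError("no included vertices")
    if grid_H is None:
        grid_H = _robust_grid(h, 512)
    if grid_K is None:
        grid_K = _robust_grid(k, 512)
    return kde_1d(h, grid_H), kde_1d(k, grid_K)


def map_to_slices(mesh: SurfaceMesh, labels: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Rasterise per-vertex region labels back onto the voxel grid.

    Each vertex maps to its nearest voxel; a voxel's label is the majority
    region among its vertices (ties to the lower region index); voxels
    without vertices are 0.  Excluded-vertex labels (0) do not vote.
    """
    idx = np.rint(mesh.vertices / mesh.spacing).astype(np.int64)
    if (idx < 0).any() or (idx >= np.asarray(shape)).any():
        raise ValueError("mesh vertices fall outside the requested volume shape")
    out = np.zeros(shape, dtype=np.uint8)
    voting = labels > 0
    if not voting.any():
        return out
    flat = np.ravel_multi_index(tuple(idx[voting].T), shape)
    lab = labels[voting].astype(np.int64)
    # count votes per (voxel, label); majority with ties to lower label
    key = flat * 5 + lab
    uniq, cnt = np.unique(key, return_counts=True)
    vox = uniq // 5
    lbl = uniq % 5
    order = np.lexsort((lbl, -cnt, vox))  # per voxel: highest count first, lower label on ties
    vox_o = vox[order]
    first = np.ones(len(vox_o), dtype=bool)
    first[1:] = vox_o[1:] != vox_o[:-1]
    out.ravel()[vox_o[first]] = lbl[order][first]
    return out


def ensemble_isd(isds: list[ISDensity]) -> tuple[ISDensity, np.ndarray]:
    """Pointwise mean ISD and std across segmentation variants (common grid)."""
    if not isds:
        raise ValueError("empty ensemble")
    g1, g2 = isds[0].grid_k1, isds[0].grid_k2
    for d in isds[1:]:
        if d.density.shape != isds[0].density.shape or not (np.allclose(d.grid_k1, g1) and np.allclose(d.grid_k2, g2)):
            raise ValueError("ISD ensemble members use inconsistent grids")
    stack = np.stack([d.density for d in isds])
    std = stack.std(axis=0, ddof=1) if len(isds) > 1 else np.zeros_like(stack[0])
    mean = ISDensity(g1, g2, stack.mean(axis=0), isds[0].bandwidth, sum(d.n_vertices for d in isds))
    return mean, std
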