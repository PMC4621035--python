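"""Per-residue metaball surfaces and the residue-residue contact-area matrix.

Each residue gets its own smooth implicit surface built from quadratic
per-atom density kernels, triangulated by marching cubes.  Two residues are
in contact wherever their meshes approach within a cutoff; the contact area
a[l][m] is the summed triangle area on *both* meshes inside the cutoff.
Buried inter-residue interfaces contribute surface precisely because each
residue is meshed alone — that is what makes the areas informative.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .config import SurfaceParams, radius_table_hash
from .structure import ChainStructure, ResidueRecord


@dataclasses.dataclass
class SurfaceMesh:
    """Triangulated isosurface of one residue."""

    vertices: np.ndarray        # (nv, 3) Å
    triangles: np.ndarray       # (nt, 3) vertex indices
    triangle_areas: np.ndarray  # (nt,) Å²

    @property
    def total_area(self) -> float:
        return float(self.triangle_areas.sum())

    def centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)


@dataclasses.dataclass
class ContactAreaMatrix:
    """Symmetric matrix of inter-residue contact areas (Å²), zero diagonal."""

    a: np.ndarray
    params: SurfaceParams = dataclasses.field(default_factory=SurfaceParams)

    @property
    def n(self) -> int:
        return self.a.shape[0]

    @property
    def total_area(self) -> float:
        """T: the sum of a[l][m] over unordered residue pairs l < m."""
        return float(np.triu(self.a, k=1).sum())


def density_at_point(x, residue: ResidueRecord, c: float = 1.5) -> float:
    """Metaball density f(x) of one residue at a point.

    Each atom i with centre g_i and van der Waals radius r_i contributes
    ``((c*r_i - |x-g_i|)^2 / (c*r_i - r_i)^2)`` while ``|x-g_i| < c*r_i``
    and zero beyond; the surface is the level set f(x) = 1, which for an
    isolated atom passes exactly through |x-g_i| = r_i.
    """
    if c <= 1:
        raise ValueError("smoothness coefficient c must exceed 1")
    x = np.asarray(x, dtype=float)
    coords = residue.coords()
    radii = residue.radii()
    d = np.linalg.norm(coords - x, axis=1)
    reach = c * radii
    inside = d < reach
    g = np.zeros_like(d)
    g[inside] = ((reach[inside] - d[inside]) ** 2
                 / (reach[inside] - radii[inside]) ** 2)
    return float(g.sum())


def _density_grid(coords: np.ndarray, radii: np.ndarray, voxel: float,
                  c: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample the residue density on a padded regular grid.

    The grid origin is the padded bounding-box minimum of this residue (not a
    global lattice), so rigid motions of the chain perturb areas only at the
    grid-discretisation level.
    """
    pad = c * radii.max() + 2.0 * voxel
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / voxel).astype(int) + 1
    axes = [lo[k] + voxel * np.arange(shape[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    density = np.zeros(len(pts))
    reach = c * radii
    denom = (reach - radii) ** 2
    for g, rc, dn in zip(coords, reach, denom):
        d = np.linalg.norm(pts - g, axis=1)
        inside = d < rc
        density[inside] += (rc - d[inside]) ** 2 / dn
    return density.reshape(shape), lo


def residue_surface_mesh(residue: ResidueRecord, voxel: float = 1.0,
                         c: float = 1.5) -> SurfaceMesh:
    """Triangulate the f(x)=1 isosurface of one residue by marching cubes."""
    coords = residue.coords()
    radii = residue.radii()
    if len(coords) == 0:
        raise ValueError("residue has no atoms")
    volume, origin = _density_grid(coords, radii, voxel, c)
    verts, faces, _, _ = marching_cubes(volume, level=1.0,
                                        spacing=(voxel, voxel, voxel))
    verts = verts + origin
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    assert len(faces) > 0, "marching cubes produced an empty mesh"
    return SurfaceMesh(vertices=verts, triangles=faces, triangle_areas=areas)


def contact_area_matrix(structure: ChainStructure,
                        params: SurfaceParams | None = None) -> ContactAreaMatrix:
    """Residue-residue contact-area matrix of one chain.

    A triangle of residue l is a contact triangle with residue m iff its
    centroid lies within ``params.cutoff`` of the nearest *vertex* of m's
    mesh; a[l][m] sums the areas of l's contact triangles with m plus the
    symmetric term on m's mesh, making the matrix symmetric by construction.
    """
    params = params or SurfaceParams()
    n = len(structure)
    meshes = [residue_surface_mesh(res, params.voxel, params.c)
              for res in structure.residues]
    centroids = [mesh.centroids() for mesh in meshes]
    trees = [cKDTree(mesh.vertices) for mesh in meshes]
    los = np.array([m.vertices.min(axis=0) for m in meshes])
    his = np.array([m.vertices.max(axis=0) for m in meshes])

    a = np.zeros((n, n))
    for l in range(n):
        for m in range(l + 1, n):
            # bounding-box prune: skip pairs whose meshes cannot approach
            gap = np.maximum(los[m] - his[l], los[l] - his[m])
            if np.linalg.norm(np.maximum(gap, 0.0)) > params.cutoff:
                continue
            d_l, _ = trees[m].query(centroids[l],
                                    distance_upper_bound=params.cutoff)
            area = meshes[l].triangle_areas[d_l <= params.cutoff].sum()
            d_m, _ = trees[l].query(centroids[m],
                                    distance_upper_bound=params.cutoff)
            area += meshes[m].triangle_areas[d_m <= params.cutoff].sum()
            a[l, m] = a[m, l] = area
    return ContactAreaMatrix(a=a, params=params)


def total_contact_area(cm: ContactAreaMatrix) -> float:
    """T: total inter-residue contact area, each unordered pair counted once."""
    return cm.total_area


# ---------------------------------------------------------------------------
# Contact-matrix cache (plain TSV so the precalculation can be shipped/diffed)

def write_contact_tsv(cm: ContactAreaMatrix, path: str | Path,
                      radius_hash: str | None = None) -> None:
    """Cache a contact matrix as a sparse ``l m area`` TSV with parameters."""
    p = cm.params
    lines = [
        f"# voxel={p.voxel} c={p.c} cutoff={p.cutoff} "
        f"radius_table={radius_hash or radius_table_hash()} n={cm.n}",
        "l\tm\tarea",
    ]
    for l, m in zip(*np.nonzero(np.triu(cm.a, k=1))):
        lines.append(f"{l}\t{m}\t{cm.a[l, m]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_contact_tsv(path: str | Path) -> ContactAreaMatrix:
    text = Path(path).read_text().splitlines()
    header = text[0]
    if not header.startswith("#"):
        raise ValueError(f"{path}: missing parameter header")
    meta = dict(tok.split("=", 1) for tok in header[1:].split() if "=" in tok)
    n = int(meta["n"])
    params = SurfaceParams(c=float(meta["c"]), voxel=float(meta["voxel"]),
                           cutoff=float(meta["cutoff"]))
    a = np.zeros((n, n))
    for line in text[2:]:
        if not line.strip():
            continue
        l, m, area = line.split("\t")
        a[int(l), int(m)] = a[int(m), int(l)] = float(area)
    return ContactAreaMatrix(a=a, params=params)
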