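"""Nuclear compartment assignment, morphometrics, and per-patch features.

'Other'-class nuclei are split by the epithelium mask into intra-epithelial
lymphocytes (IEL, centroid on an epithelium pixel) and peri-epithelial
lymphocytes (PEL, centroid in stroma); epithelial classes pass through.
Each scoring patch is summarized by a 168-value feature vector combining
per-class morphology (counts, densities, moments of shape measures) and
spatial statistics (nearest-neighbour distances, Delaunay graph structure,
area fractions, class-mixing indices).

Statistics over empty sets are imputed as 0; the companion count feature
makes imputed zeros distinguishable from measured ones.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon

from odyn.datamodel import MaskRaster, NucleusInstance

logger = logging.getLogger(__name__)

COMPARTMENT_CLASSES = ("dysplastic_epithelial", "normal_epithelial", "IEL", "PEL")

MORPHOMETRIC_NAMES = (
    "area_um2",
    "perimeter_um",
    "circularity",
    "eccentricity",
    "major_axis_um",
    "minor_axis_um",
    "solidity",
    "equivalent_diameter_um",
)

N_FEATURES = 168


@dataclass(frozen=True)
class CompartmentNucleus:
    """A nucleus with its compartment class resolved against the epithelium."""

    nucleus: NucleusInstance
    compartment_class: str

    @property
    def centroid(self) -> tuple[float, float]:
        return self.nucleus.centroid


def assign_compartment(nucleus: NucleusInstance, epithelium: MaskRaster) -> CompartmentNucleus:
    """Resolve 'other' nuclei to IEL/PEL by the epithelium pixel under the
    centroid; epithelial raw classes pass through unchanged."""
    if nucleus.raw_class != "other":
        return CompartmentNucleus(nucleus, nucleus.raw_class)
    x, y = nucleus.centroid
    col = int(np.clip(round(x), 0, epithelium.shape[1] - 1))
    row = int(np.clip(round(y), 0, epithelium.shape[0] - 1))
    cls = "IEL" if epithelium.pixels[row, col] else "PEL"
    return CompartmentNucleus(nucleus, cls)


def assign_compartments(
    nuclei: list[NucleusInstance], epithelium: MaskRaster
) -> list[CompartmentNucleus]:
    return [assign_compartment(n, epithelium) for n in nuclei]


# ---------------------------------------------------------------------------
# morphometrics


def nucleus_morphometrics(contour: np.ndarray, mpp: float = 1.0) -> dict[str, float]:
    """Shape measures of one nuclear contour, converted to microns via mpp.

    Emits area (µm²), perimeter (µm), circularity 4πA/P², eccentricity and
    major/minor axis lengths of the ellipse with matching normalized second
    central moments, solidity, and equivalent diameter. Self-intersecting
    polygons are repaired by a convex-hull fallback (logged).
    """
    poly = Polygon(np.asarray(contour, dtype=float))
    if not poly.is_valid:
        logger.info("self-intersecting contour repaired by convex hull")
        poly = poly.convex_hull
    area_px = poly.area
    perim_px = poly.length
    hull_area = poly.convex_hull.area
    cx, cy = poly.centroid.x, poly.centroid.y
    verts = np.asarray(poly.exterior.coords)[:-1] - (cx, cy)

    # exact second central moments of the uniform polygon (shoelace forms)
    x, y = verts[:, 0], verts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a_signed = cross.sum() / 2.0
    if abs(a_signed) < 1e-12:
        mu_xx = mu_yy = mu_xy = 0.0
    else:
        mu_xx = (cross * (x**2 + x * x1 + x1**2)).sum() / 12.0 / a_signed
        mu_yy = (cross * (y**2 + y * y1 + y1**2)).sum() / 12.0 / a_signed
        mu_xy = (cross * (x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y)).sum() / 24.0 / a_signed
    cov = np.array([[mu_xx, mu_xy], [mu_xy, mu_yy]])
    lam = np.sort(np.clip(np.linalg.eigvalsh(cov), 0.0, None))  # λ2 <= λ1
    major = 4.0 * np.sqrt(lam[1])
    minor = 4.0 * np.sqrt(lam[0])
    ecc = float(np.sqrt(1.0 - lam[0] / lam[1])) if lam[1] > 0 else 0.0

    circ = 4.0 * np.pi * area_px / perim_px**2 if perim_px > 0 else 0.0
    return {
        "area_um2": area_px * mpp**2,
        "perimeter_um": perim_px * mpp,
        "circularity": float(circ),
        "eccentricity": ecc,
        "major_axis_um": major * mpp,
        "minor_axis_um": minor * mpp,
        "solidity": area_px / hull_area if hull_area > 0 else 0.0,
        "equivalent_diameter_um": 2.0 * np.sqrt(area_px / np.pi) * mpp,
    }


# ---------------------------------------------------------------------------
# feature registry


class FeatureRegistry:
    """Ordered definition of the per-patch feature vector.

    The default registry emits exactly 168 features:

    * per compartment class (4): count and density (per mm²), plus mean and
      standard deviation of each of the 8 morphometrics — 4 × 18 = 72;
    * per class (4): within-class nearest-neighbour distance mean/sd/min,
      Delaunay node degree mean/sd, Delaunay incident-edge length
      mean/sd/min, nuclear area fraction — 4 × 9 = 36;
    * per ordered class pair (12): nearest cross-class neighbour distance
      mean/sd/min — 12 × 3 = 36;
    * per unordered class pair (6): Delaunay cross-edge fraction and
      k-nearest-neighbour mixing index — 6 × 2 = 12;
    * global (12): total count, total density, the 4 class shares, overall
      nearest-neighbour distance mean/sd/min, Delaunay degree mean/sd, and
      Delaunay edge-length mean.

    The registry is serializable so an alternative feature list can be
    slotted in without code changes (names and block structure are data).
    """

    def __init__(self, classes: tuple[str, ...] = COMPARTMENT_CLASSES,
                 morphometrics: tuple[str, ...] = MORPHOMETRIC_NAMES,
                 knn_k: int = 5):
        self.classes = tuple(classes)
        self.morphometrics = tuple(morphometrics)
        self.knn_k = int(knn_k)
        self.names = self._build_names()

    def _build_names(self) -> list[str]:
        names: list[str] = []
        for c in self.classes:
            names += [f"{c}__count", f"{c}__density_per_mm2"]
            for m in self.morphometrics:
                names += [f"{c}__{m}__mean", f"{c}__{m}__sd"]
        for c in self.classes:
            names += [
                f"{c}__nn_dist_um__mean", f"{c}__nn_dist_um__sd", f"{c}__nn_dist_um__min",
                f"{c}__delaunay_degree__mean", f"{c}__delaunay_degree__sd",
                f"{c}__delaunay_edge_um__mean", f"{c}__delaunay_edge_um__sd",
                f"{c}__delaunay_edge_um__min",
                f"{c}__area_fraction",
            ]
        for a in self.classes:
            for b in self.classes:
                if a != b:
                    names += [
                        f"{a}_to_{b}__nn_dist_um__mean",
                        f"{a}_to_{b}__nn_dist_um__sd",
                        f"{a}_to_{b}__nn_dist_um__min",
                    ]
        for i, a in enumerate(self.classes):
            for b in self.classes[i + 1:]:
                names += [f"{a}__{b}__delaunay_mix", f"{a}__{b}__knn_mix"]
        names += [
            "all__count", "all__density_per_mm2",
            *[f"share__{c}" for c in self.classes],
            "all__nn_dist_um__mean", "all__nn_dist_um__sd", "all__nn_dist_um__min",
            "all__delaunay_degree__mean", "all__delaunay_degree__sd",
            "all__delaunay_edge_um__mean",
        ]
        return names

    def __len__(self) -> int:
        return len(self.names)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"classes": self.classes, "morphometrics": self.morphometrics,
                 "knn_k": self.knn_k, "names": self.names, "version": 1},
                fh, indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureRegistry":
        with open(path) as fh:
            d = json.load(fh)
        reg = cls(tuple(d["classes"]), tuple(d["morphometrics"]), d["knn_k"])
        if reg.names != d["names"]:
            raise ValueError("registry file inconsistent with its structural fields")
        return reg


DEFAULT_REGISTRY = FeatureRegistry()
assert len(DEFAULT_REGISTRY) == N_FEATURES


# ---------------------------------------------------------------------------
# per-patch feature vector


def _stats(v: np.ndarray, keys: tuple[str, ...]) -> list[float]:
    """Imputation rule: statistics over empty sets are 0."""
    if v.size == 0:
        return [0.0] * len(keys)
    out = []
    for k in keys:
        if k == "mean":
            out.append(float(np.mean(v)))
        elif k == "sd":
            out.append(float(np.std(v)))
        elif k == "min":
            out.append(float(np.min(v)))
    return out


def _nn_distances(src: np.ndarray, dst: np.ndarray, same: bool) -> np.ndarray:
    """Distance from each src point to its nearest dst point (self excluded)."""
    if len(src) == 0 or len(dst) < (2 if same else 1):
        return np.empty(0)
    tree = cKDTree(dst)
    k = 2 if same else 1
    d, _ = tree.query(src, k=k)
    return d[:, -1] if k == 2 else np.atleast_1d(d)


def _delaunay_edges(pts: np.ndarray) -> np.ndarray:
    """Unique undirected edges (i, j) of the Delaunay triangulation."""
    if len(pts) < 3:
        return np.empty((0, 2), dtype=int)
    try:
        tri = Delaunay(pts)
    except Exception:  # degenerate (collinear) point sets
        return np.empty((0, 2), dtype=int)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            edges.add((min(a, b), max(a, b)))
    return np.array(sorted(edges), dtype=int) if edges else np.empty((0, 2), dtype=int)


def patch_features(
    window: tuple[int, int, int],
    nuclei: list[CompartmentNucleus],
    mpp: float,
    registry: FeatureRegistry = DEFAULT_REGISTRY,
) -> np.ndarray:
    """Compute the feature vector for one patch.

    ``window`` is (x_origin, y_origin, patch_size) in pixels at ``mpp``; a
    nucleus belongs to the patch iff its centroid lies in the half-open
    window. Empty patches yield the all-zero vector.
    """
    x0, y0, size = window
    inside = [
        n for n in nuclei
        if x0 <= n.centroid[0] < x0 + size and y0 <= n.centroid[1] < y0 + size
    ]
    patch_area_mm2 = (size * mpp / 1000.0) ** 2
    patch_area_um2 = (size * mpp) ** 2
    values: list[float] = []

    by_class = {c: [n for n in inside if n.compartment_class == c] for c in registry.classes}
    morpho = {
        c: [nucleus_morphometrics(n.nucleus.contour, mpp) for n in by_class[c]]
        for c in registry.classes
    }

    # morphological block
    for c in registry.classes:
        ms = morpho[c]
        values += [float(len(ms)), len(ms) / patch_area_mm2]
        for m in registry.morphometrics:
            v = np.array([row[m] for row in ms])
            values += _stats(v, ("mean", "sd"))

    pts = {c: np.array([n.centroid for n in by_class[c]], dtype=float).reshape(-1, 2)
           for c in registry.classes}
    all_pts = np.array([n.centroid for n in inside], dtype=float).reshape(-1, 2)
    all_cls = np.array([n.compartment_class for n in inside])
    edges = _delaunay_edges(all_pts)
    degree = np.zeros(len(all_pts))
    if len(edges):
        np.add.at(degree, edges[:, 0], 1)
        np.add.at(degree, edges[:, 1], 1)
    edge_len_um = (
        np.linalg.norm(all_pts[edges[:, 0]] - all_pts[edges[:, 1]], axis=1) * mpp
        if len(edges) else np.empty(0)
    )

    # per-class spatial block
    for c in registry.classes:
        nn = _nn_distances(pts[c], pts[c], same=True) * mpp
        values += _stats(nn, ("mean", "sd", "min"))
        idx = np.flatnonzero(all_cls == c)
        values += _stats(degree[idx], ("mean", "sd"))
        if len(edges):
            incident = np.isin(edges[:, 0], idx) | np.isin(edges[:, 1], idx)
            values += _stats(edge_len_um[incident], ("mean", "sd", "min"))
        else:
            values += [0.0, 0.0, 0.0]
        class_area = sum(row["area_um2"] for row in morpho[c])
        values.append(class_area / patch_area_um2)

    # ordered cross-class nearest-neighbour distances
    for a in registry.classes:
        for b in registry.classes:
            if a != b:
                d = _nn_distances(pts[a], pts[b], same=False) * mpp
                values += _stats(d, ("mean", "sd", "min"))

    # unordered pair mixing indices
    for i, a in enumerate(registry.classes):
        for b in registry.classes[i + 1:]:
            if len(edges):
                ca, cb = all_cls[edges[:, 0]], all_cls[edges[:, 1]]
                cross = ((ca == a) & (cb == b)) | ((ca == b) & (cb == a))
                values.append(float(cross.mean()))
            else:
                values.append(0.0)
            values.append(_knn_mixing(pts[a], pts[b], registry.knn_k))

    # global block
    n_all = len(inside)
    values += [float(n_all), n_all / patch_area_mm2]
    values += [len(by_class[c]) / n_all if n_all else 0.0 for c in registry.classes]
    nn_all = _nn_distances(all_pts, all_pts, same=True) * mpp
    values += _stats(nn_all, ("mean", "sd", "min"))
    values += _stats(degree if n_all else np.empty(0), ("mean", "sd"))
    values += _stats(edge_len_um, ("mean",))

    vec = np.asarray(values, dtype=float)
    if len(vec) != len(registry):
        raise RuntimeError(f"registry emitted {len(vec)} features, expected {len(registry)}")
    if not np.all(np.isfinite(vec)):
        raise RuntimeError("non-finite feature value escaped imputation")
    return vec


def _knn_mixing(pa: np.ndarray, pb: np.ndarray, k: int) -> float:
    """Fraction of k-nearest-neighbour links within classes a∪b that cross
    between the classes; 0 when fewer than two nuclei are present."""
    pool = np.vstack([pa, pb])
    labels = np.array([0] * len(pa) + [1] * len(pb))
    n = len(pool)
    if n < 2:
        return 0.0
    kk = min(k, n - 1)
    tree = cKDTree(pool)
    _, idx = tree.query(pool, k=kk + 1)
    idx = np.atleast_2d(idx)[:, 1:]  # drop self
    cross = labels[idx] != labels[:, None]
    return float(cross.mean())


def slide_feature_matrix(
    grid,
    nuclei: list[CompartmentNucleus],
    nuclei_mpp: float,
    registry: FeatureRegistry = DEFAULT_REGISTRY,
) -> np.ndarray:
    """Feature vectors for every patch of a grid, as an (n_patches, 168) array.

    Nucleus coordinates (given at ``nuclei_mpp``) are rescaled to the
    grid's target resolution before window membership is evaluated.
    """
    factor = nuclei_mpp / grid.target_mpp
    if not np.isclose(factor, 1.0):
        nuclei = [
            CompartmentNucleus(
                NucleusInstance(
                    n.nucleus.nucleus_id, n.nucleus.raw_class,
                    n.nucleus.contour * factor,
                    (n.centroid[0] * factor, n.centroid[1] * factor),
                ),
                n.compartment_class,
            )
            for n in nuclei
        ]
    rows = [
        patch_features((x, y, grid.patch_size), nuclei, grid.target_mpp, registry)
        for x, y in grid.origins
    ]
    return np.array(rows).reshape(len(grid.origins), len(registry))
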