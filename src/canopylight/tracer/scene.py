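"""Triangle-soup scene index: tags, BVH and virtual sensor placement."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..synthetic import CanopyScene

__all__ = ["SceneIndex", "SensorSet", "build_index", "build_sensors"]

_LEAF_BVH_SIZE = 4


@dataclass
class SensorSet:
    """Passive detector disks offset from the leaf reference points.

    Each leaf contributes three reference points per side; the sensor
    center sits ``offset`` along the local adaxial normal (+ for adaxial,
    - for abaxial) and faces away from the lamina.  Sensors never occlude
    or scatter rays.
    """

    centers: np.ndarray      # (ns, 3)
    normals: np.ndarray      # (ns, 3) facing direction
    radius: float
    plant: np.ndarray        # (ns,)
    leaf_order: np.ndarray   # (ns,)
    side: np.ndarray         # (ns,) 0 adaxial / 1 abaxial
    point_id: np.ndarray     # (ns,) 0 centroid, 1 third, 2 two-thirds

    @property
    def n_sensors(self) -> int:
        return len(self.centers)

    @property
    def area(self) -> float:
        return float(np.pi * self.radius ** 2)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(
            sensor_id=np.arange(self.n_sensors), plant=self.plant,
            leaf_order=self.leaf_order,
            side=np.where(self.side == 0, "adaxial", "abaxial"),
            point_id=self.point_id))


@dataclass
class SceneIndex:
    """Tagged triangles plus a BVH and the scene bounding sphere."""

    v0: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    group: np.ndarray        # (T,) leaf group id = plant*5 + order-1; -1 stem
    plant_of_tri: np.ndarray
    n_groups: int
    n_plants: int
    # BVH arrays (flattened nodes)
    node_min: np.ndarray = field(default=None)
    node_max: np.ndarray = field(default=None)
    node_left: np.ndarray = field(default=None)
    node_right: np.ndarray = field(default=None)
    node_start: np.ndarray = field(default=None)
    node_count: np.ndarray = field(default=None)
    tri_order: np.ndarray = field(default=None)
    ground_radius: float = 0.0
    sphere_center: np.ndarray = field(default=None)
    sphere_radius: float = 0.0

    @property
    def n_triangles(self) -> int:
        return len(self.v0)

    def group_frame(self) -> pd.DataFrame:
        g = np.arange(self.n_groups)
        return pd.DataFrame(dict(group=g, plant=g // 5, leaf_order=g % 5 + 1))


def _build_bvh(v0, v1, v2):
    n = len(v0)
    lo = np.minimum(np.minimum(v0, v1), v2)
    hi = np.maximum(np.maximum(v0, v1), v2)
    centroid = (lo + hi) / 2.0

    node_min, node_max = [], []
    node_left, node_right, node_start, node_count = [], [], [], []
    order = []

    def make_node(idx):
        node_id = len(node_min)
        node_min.append(lo[idx].min(axis=0))
        node_max.append(hi[idx].max(axis=0))
        node_left.append(-1)
        node_right.append(-1)
        node_start.append(-1)
        node_count.append(0)
        if len(idx) <= _LEAF_BVH_SIZE:
            node_start[node_id] = len(order)
            node_count[node_id] = len(idx)
            order.extend(idx.tolist())
            return node_id
        ext = node_max[node_id] - node_min[node_id]
        axis = int(np.argmax(ext))
        med = np.median(centroid[idx, axis])
        left_mask = centroid[idx, axis] <= med
        if left_mask.all() or not left_mask.any():
            left_mask = np.zeros(len(idx), dtype=bool)
            left_mask[: len(idx) // 2] = True
            sort = np.argsort(centroid[idx, axis])
            idx = idx[sort]
        node_left[node_id] = make_node(idx[left_mask])
        node_right[node_id] = make_node(idx[~left_mask])
        return node_id

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000))
    try:
        make_node(np.arange(n))
    finally:
        sys.setrecursionlimit(old)
    return (np.asarray(node_min), np.asarray(node_max),
            np.asarray(node_left, dtype=np.int32),
            np.asarray(node_right, dtype=np.int32),
            np.asarray(node_start, dtype=np.int32),
            np.asarray(node_count, dtype=np.int32),
            np.asarray(order, dtype=np.int32))


def build_index(scene: CanopyScene,
                extra_points: np.ndarray | None = None) -> SceneIndex:
    """Flatten a canopy into tagged triangles and build the BVH."""
    v0s, v1s, v2s, groups, plants = [], [], [], [], []
    for i, (plant, pos) in enumerate(zip(scene.plants, scene.positions)):
        off = np.array([pos[0], pos[1], 0.0])
        for leaf in plant.leaves:
            v = leaf.vertices + off
            f = leaf.faces
            v0s.append(v[f[:, 0]]); v1s.append(v[f[:, 1]]); v2s.append(v[f[:, 2]])
            gid = i * 5 + (leaf.order - 1)
            groups.append(np.full(len(f), gid, dtype=np.int32))
            plants.append(np.full(len(f), i, dtype=np.int32))
        v = plant.stem_vertices + off
        f = plant.stem_faces
        v0s.append(v[f[:, 0]]); v1s.append(v[f[:, 1]]); v2s.append(v[f[:, 2]])
        groups.append(np.full(len(f), -1, dtype=np.int32))
        plants.append(np.full(len(f), i, dtype=np.int32))
    if not v0s:
        raise ValueError("cannot index an empty scene")
    v0 = np.ascontiguousarray(np.concatenate(v0s))
    v1 = np.ascontiguousarray(np.concatenate(v1s))
    v2 = np.ascontiguousarray(np.concatenate(v2s))
    group = np.concatenate(groups)
    plant_of = np.concatenate(plants)
    bvh = _build_bvh(v0, v1, v2)
    pts = np.concatenate([v0, v1, v2] +
                         ([extra_points] if extra_points is not None else []))
    center = (pts.min(axis=0) + pts.max(axis=0)) / 2.0
    radius = float(np.linalg.norm(pts - center, axis=1).max()) + 0.02
    return SceneIndex(v0, v1, v2, group, plant_of,
                      n_groups=scene.n_plants * 5, n_plants=scene.n_plants,
                      node_min=np.ascontiguousarray(bvh[0]),
                      node_max=np.ascontiguousarray(bvh[1]),
                      node_left=bvh[2], node_right=bvh[3],
                      node_start=bvh[4], node_count=bvh[5], tri_order=bvh[6],
                      ground_radius=scene.ground_radius,
                      sphere_center=center, sphere_radius=radius)


def index_from_triangles(v0, v1, v2, group, plant_of, n_groups, n_plants,
                         ground_radius=0.0,
                         extra_points: np.ndarray | None = None) -> SceneIndex:
    """Low-level constructor for ad-hoc scenes (tests, validation rigs)."""
    v0, v1, v2 = (np.ascontiguousarray(np.atleast_2d(a), dtype=float)
                  for a in (v0, v1, v2))
    bvh = _build_bvh(v0, v1, v2)
    pts = np.concatenate([v0, v1, v2] +
                         ([np.atleast_2d(extra_points)]
                          if extra_points is not None else []))
    center = (pts.min(axis=0) + pts.max(axis=0)) / 2.0
    radius = float(np.linalg.norm(pts - center, axis=1).max()) + 0.02
    return SceneIndex(v0, v1, v2,
                      np.asarray(group, dtype=np.int32),
                      np.asarray(plant_of, dtype=np.int32),
                      n_groups=n_groups, n_plants=n_plants,
                      node_min=np.ascontiguousarray(bvh[0]),
                      node_max=np.ascontiguousarray(bvh[1]),
                      node_left=bvh[2], node_right=bvh[3],
                      node_start=bvh[4], node_count=bvh[5], tri_order=bvh[6],
                      ground_radius=ground_radius,
                      sphere_center=center, sphere_radius=radius)


def build_sensors(scene: CanopyScene, offset: float = 0.005,
                  radius: float = 0.0025,
                  plants: str = "central") -> SensorSet:
    """Place three sensor disks per leaf side, 5 mm off the lamina.

    ``plants`` selects which plants carry sensors: 'central' (the
    arrangement's central set, the paper's analysis population) or 'all'.
    """
    if plants == "central":
        plant_ids = scene.central_indices
    elif plants == "all":
        plant_ids = tuple(range(scene.n_plants))
    else:
        raise ValueError("plants must be 'central' or 'all'")
    centers, normals, plant_l, order_l, side_l, pid_l = [], [], [], [], [], []
    for i in plant_ids:
        plant = scene.plants[i]
        off3 = np.array([scene.positions[i][0], scene.positions[i][1], 0.0])
        for leaf in plant.leaves:
            for k in range(3):
                p = leaf.ref_points[k] + off3
                n = leaf.ref_normals[k]
                n = n / np.linalg.norm(n)
                for side, sgn in ((0, 1.0), (1, -1.0)):
                    centers.append(p + sgn * offset * n)
                    normals.append(sgn * n)
                    plant_l.append(i)
                    order_l.append(leaf.order)
                    side_l.append(side)
                    pid_l.append(k)
    return SensorSet(np.asarray(centers), np.asarray(normals), radius,
                     np.asarray(plant_l, dtype=np.int32),
                     np.asarray(order_l, dtype=np.int32),
                     np.asarray(side_l, dtype=np.int32),
                     np.asarray(pid_l, dtype=np.int32))
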