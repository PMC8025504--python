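"""Rest-event credible ellipses, spatial joining and reuse detection.

Each rest event gets a Gaussian credible ellipse: within a rest event the
smoothing distribution of the (constant) location is exactly Gaussian, so
the ellipse from the pooled draws' mean and covariance, with axes scaled by
the square root of the chi-square(2 df) quantile, is the model-consistent
credible region.  Events whose 95% ellipses overlap (directly or through a
chain of overlaps) are joined into one geographically distinct rest
location, the unit for reuse analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2
from shapely.geometry import Point, Polygon, mapping
from shapely.ops import unary_union

from .hmm import RestEvent
from .ssm import LatentPathDraws

__all__ = [
    "CredibleEllipse",
    "RestLocationCluster",
    "rest_event_ellipse",
    "ellipses_overlap",
    "cluster_rest_locations",
    "detect_reuse",
    "distance_to_ellipse_edge",
    "ellipses_to_geojson",
]

DEFAULT_VERTICES = 64
MIN_DRAWS = 30


@dataclass(frozen=True)
class CredibleEllipse:
    """A credible ellipse for one rest event's location.

    Axes are the semi-major/semi-minor lengths in meters; orientation is the
    angle of the major axis from east, radians in (-pi/2, pi/2]; area is in
    hectares (pi * a * b / 10^4).
    """

    event: RestEvent
    level: float
    center: tuple
    semi_major: float
    semi_minor: float
    orientation: float
    area_ha: float
    polygon: Polygon = field(repr=False, compare=False)


@dataclass(frozen=True)
class RestLocationCluster:
    """One geographically distinct rest location (chain-overlap component)."""

    location_id: int
    events: tuple
    animal_ids: tuple
    footprint: Polygon = field(repr=False, compare=False)
    revisited: bool = False
    multi_animal: bool = False
    median_revisit_gap_days: float = float("nan")

    @property
    def n_events(self) -> int:
        return len(self.events)


def _event_locations(draws: LatentPathDraws, event: RestEvent) -> np.ndarray:
    """One location per draw for the event (constant within the event under
    the resting constraint; the event's first step is used)."""
    return draws.paths[:, event.start_index, :]


def ellipse_from_points(points: np.ndarray, level: float,
                        n_vertices: int = DEFAULT_VERTICES,
                        event: RestEvent | None = None) -> CredibleEllipse:
    """Gaussian credible ellipse from a cloud of location draws."""
    pts = np.asarray(points, float)
    if pts.shape[0] < MIN_DRAWS:
        raise ValueError(
            f"need at least {MIN_DRAWS} draws for a stable covariance, "
            f"got {pts.shape[0]}"
        )
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    if not np.all(np.isfinite(cov)) or np.linalg.det(cov) <= 0:
        raise ValueError("degenerate ellipse: draw covariance is singular")
    w, V = np.linalg.eigh(cov)
    if w[0] <= 0:
        raise ValueError("degenerate ellipse: draw covariance is singular")
    c = chi2.ppf(level, df=2)
    semi_minor, semi_major = np.sqrt(w * c)
    major_vec = V[:, 1]
    orientation = np.arctan2(major_vec[1], major_vec[0])
    if orientation <= -np.pi / 2:
        orientation += np.pi
    elif orientation > np.pi / 2:
        orientation -= np.pi
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    ring = (
        center[None, :]
        + np.outer(np.cos(theta) * semi_major, V[:, 1])
        + np.outer(np.sin(theta) * semi_minor, V[:, 0])
    )
    return CredibleEllipse(
        event=event, level=level, center=(float(center[0]), float(center[1])),
        semi_major=float(semi_major), semi_minor=float(semi_minor),
        orientation=float(orientation),
        area_ha=float(np.pi * semi_major * semi_minor / 1e4),
        polygon=Polygon(ring),
    )


def rest_event_ellipse(draws: LatentPathDraws, event: RestEvent,
                       level: float = 0.95,
                       n_vertices: int = DEFAULT_VERTICES) -> CredibleEllipse:
    """Credible ellipse for one rest event, pooling one location per draw."""
    if event.end_index >= draws.paths.shape[1]:
        raise ValueError("draws do not cover the rest event")
    return ellipse_from_points(
        _event_locations(draws, event), level, n_vertices, event=event
    )


def ellipses_overlap(a: CredibleEllipse, b: CredibleEllipse) -> bool:
    """Whether the two boundary polygons' interiors intersect."""
    if a.level != b.level:
        raise ValueError("ellipses must be at the same credible level")
    return bool(a.polygon.intersects(b.polygon))


def cluster_rest_locations(ellipses: list[CredibleEllipse]) -> list[RestLocationCluster]:
    """Connected components of the pairwise-overlap graph of 95% ellipses.

    The "spatial join" is transitive: two events belong to one location if a
    chain of pairwise-overlapping ellipses connects them.  Output is sorted
    by earliest event start time, so it is independent of input order.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(ellipses)))
    from shapely.strtree import STRtree

    polys = [e.polygon for e in ellipses]
    if polys:
        tree = STRtree(polys)
        for i, p in enumerate(polys):
            for j in tree.query(p, predicate="intersects"):
                if int(j) > i:
                    g.add_edge(i, int(j))
    comps = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda i: ellipses[i].event.start_time)
        evs = tuple(ellipses[i].event for i in members)
        comps.append((evs, unary_union([polys[i] for i in members])))
    comps.sort(key=lambda c: (c[0][0].start_time, c[0][0].deployment_id))
    return [
        RestLocationCluster(
            location_id=k, events=evs,
            animal_ids=tuple(sorted({e.animal_id for e in evs})),
            footprint=fp,
        )
        for k, (evs, fp) in enumerate(comps)
    ]


def detect_reuse(clusters: list[RestLocationCluster],
                 min_gap_hours: float = 24.0) -> list[RestLocationCluster]:
    """Flag revisits (same animal, gap of >= 24 h between the end of one
    event and the start of the next) and multi-animal use per cluster."""
    out = []
    for cl in clusters:
        gaps = []
        by_animal: dict[str, list[RestEvent]] = {}
        for e in cl.events:
            by_animal.setdefault(e.animal_id, []).append(e)
        revisited = False
        for evs in by_animal.values():
            evs = sorted(evs, key=lambda e: e.start_time)
            for prev, nxt in zip(evs, evs[1:]):
                gap_h = (nxt.start_time - prev.end_time).total_seconds() / 3600.0
                if gap_h >= min_gap_hours:
                    revisited = True
                    gaps.append(gap_h / 24.0)
        out.append(
            RestLocationCluster(
                location_id=cl.location_id, events=cl.events,
                animal_ids=cl.animal_ids, footprint=cl.footprint,
                revisited=revisited,
                multi_animal=len(cl.animal_ids) > 1,
                median_revisit_gap_days=float(np.median(gaps)) if gaps else float("nan"),
            )
        )
    return out


def distance_to_ellipse_edge(point, ellipse: CredibleEllipse) -> float:
    """Signed distance (m) from a point to the ellipse boundary: negative
    inside, zero on the boundary, positive outside."""
    p = Point(point)
    d = p.distance(ellipse.polygon.exterior)
    return -d if ellipse.polygon.contains(p) else d


def clusters_to_frame(clusters: list[RestLocationCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "location_id": [c.location_id for c in clusters],
            "n_events": [c.n_events for c in clusters],
            "n_animals": [len(c.animal_ids) for c in clusters],
            "revisited": [c.revisited for c in clusters],
            "multi_animal": [c.multi_animal for c in clusters],
            "median_revisit_gap_days": [c.median_revisit_gap_days for c in clusters],
        }
    )


def ellipses_to_geojson(ellipses: list[CredibleEllipse], path=None) -> dict:
    """GeoJSON FeatureCollection of ellipse polygons (planar coordinates)."""
    features = []
    for e in ellipses:
        props = {
            "level": e.level,
            "area_ha": e.area_ha,
            "semi_major_m": e.semi_major,
            "semi_minor_m": e.semi_minor,
        }
        if e.event is not None:
            props.update(
                deployment_id=e.event.deployment_id,
                animal_id=e.event.animal_id,
                event_id=e.event.event_id,
                n_fixes=e.event.n_fixes,
                duration_h=e.event.duration_h,
            )
        features.append(
            {"type": "Feature", "geometry": mapping(e.polygon), "properties": props}
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc
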