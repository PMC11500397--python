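"""Shell / mantle / core zone assignment.

Every residue gets two topographic features: the number of waters it contacts
in the initial solvated frame (before any annealing) and the number of other
residues with a heavy atom within ``r_nbr``.  k-means (k=3) on the z-scored
features partitions the residues; labels are made identifiable by centroid
ordering — the centroid with the highest water count is the shell, the lowest
is the core, the remaining one the mantle (ties broken by neighbor count,
lower → shell).  Shell residues are water-exposed with few residue contacts;
core residues have minimal water contact and many residue contacts; the
mantle sits in between.  Small peptides and disordered chains may lack a core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .contacts import ContactParams, count_contacts
from .errors import DegenerateClusteringError
from .geometry import neighbor_counts

__all__ = [
    "ZoneFeatures",
    "ZoneAssignment",
    "ZONES",
    "compute_features",
    "cluster_zones",
    "zone_fractions",
    "zone_parch_summary",
]

ZONES = ("shell", "mantle", "core")


@dataclass(frozen=True)
class ZoneFeatures:
    residue_index: int
    n_water: int
    n_neighbors: int


@dataclass
class ZoneAssignment:
    """Residue → zone map plus the feature-space centroids that define it.

    ``centroids`` is keyed by zone label and holds (n_water, n_neighbors) in
    the original (unstandardised) units; ``fractions`` are percentages and sum
    to 100.
    """

    zones: dict[int, str]
    centroids: dict[str, tuple[float, float]]
    fractions: dict[str, float]
    degenerate: bool = False

    def residues_in(self, zone: str) -> list[int]:
        return sorted(i for i, z in self.zones.items() if z == zone)


def compute_features(system, params: ContactParams | None = None,
                     r_nbr: float = 5.0) -> list[ZoneFeatures]:
    """Topographic features from a solvated system.

    ``n_water`` is counted on the initial (pre-annealing) frame; zonation is a
    static property of the topography, not of the evaporation dynamics.
    """
    contacts = count_contacts(system.water_coords, system.structure, params,
                              water_ids=system.water_ids)
    nbrs = neighbor_counts(system.structure, r_nbr)
    return [
        ZoneFeatures(residue_index=i, n_water=len(contacts[i]), n_neighbors=int(nbrs[i]))
        for i in range(len(system.structure.residues))
    ]


def _feature_matrix(features: list[ZoneFeatures]) -> tuple[np.ndarray, np.ndarray]:
    idx = np.asarray([f.residue_index for f in features])
    X = np.asarray([[f.n_water, f.n_neighbors] for f in features], dtype=float)
    return idx, X


def cluster_zones(features: list[ZoneFeatures], seed: int = 0,
                  on_degenerate: str = "raise") -> ZoneAssignment:
    """k-means (k=3, 10 restarts) on z-scored (n_water, n_neighbors).

    With fewer than three distinct feature vectors the clustering is
    degenerate: ``on_degenerate='raise'`` (default) raises
    :class:`DegenerateClusteringError` carrying a flagged single-zone fallback;
    ``'single-zone'`` returns that fallback directly.
    """
    idx, X = _feature_matrix(features)
    if len(np.unique(X, axis=0)) < 3:
        fallback = ZoneAssignment(
            zones={int(i): "shell" for i in idx},
            centroids={"shell": (float(X[:, 0].mean()), float(X[:, 1].mean()))} if len(X) else {},
            fractions={"shell": 100.0, "mantle": 0.0, "core": 0.0},
            degenerate=True,
        )
        if on_degenerate == "single-zone":
            return fallback
        raise DegenerateClusteringError(
            "fewer than 3 distinct feature vectors; zones are unresolvable",
            fallback=fallback,
        )

    mu, sigma = X.mean(axis=0), X.std(axis=0)
    sigma[sigma == 0] = 1.0
    Z = (X - mu) / sigma
    km = KMeans(n_clusters=3, n_init=10, random_state=seed)
    labels = km.fit_predict(Z)
    centroids = km.cluster_centers_ * sigma + mu  # back to original units

    # identifiable labels: most water -> shell, least -> core; ties broken by
    # fewer residue neighbors -> shell
    order = sorted(range(3), key=lambda c: (-centroids[c, 0], centroids[c, 1]))
    zone_of_cluster = {order[0]: "shell", order[1]: "mantle", order[2]: "core"}

    zones = {int(i): zone_of_cluster[int(c)] for i, c in zip(idx, labels)}
    counts = {z: sum(1 for v in zones.values() if v == z) for z in ZONES}
    total = len(zones)
    return ZoneAssignment(
        zones=zones,
        centroids={zone_of_cluster[c]: (float(centroids[c, 0]), float(centroids[c, 1]))
                   for c in range(3)},
        fractions={z: 100.0 * counts[z] / total for z in ZONES},
    )


def zone_fractions(assignment: ZoneAssignment) -> tuple[float, float, float]:
    """(pct_shell, pct_mantle, pct_core); sums to 100."""
    return tuple(assignment.fractions.get(z, 0.0) for z in ZONES)


def zone_parch_summary(results, assignment: ZoneAssignment) -> dict[str, dict[str, float]]:
    """Mean/SD/min/max of parch per zone; zones with no residues are absent.

    Peptides and disordered chains may lack a core — an empty zone is reported
    as missing, never as an error.
    """
    by_zone: dict[str, list[float]] = {z: [] for z in ZONES}
    for r in results:
        zone = assignment.zones.get(r.residue_index)
        if zone is not None:
            by_zone[zone].append(r.parch)
    out = {}
    for z, vals in by_zone.items():
        if not vals:
            continue
        arr = np.asarray(vals)
        out[z] = {
            "n": len(arr),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "min": float(arr.min()),
            "max": float(arr.max()),
        }
    return out
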