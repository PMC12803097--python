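"""Time-stratified dispersal multiplier matrices from paleogeography.

Each geologic stratum is summarized by one realm-by-realm multiplier matrix
M in [0, 1] that scales the base dispersal rate d between realm pairs.  The
pipeline per stratum: paleo-rotated realm seed points are extrapolated over
the water mask (nearest-seed Voronoi on the sphere), realm centroids are
taken as spherical means, shortest over-water paths between centroids are
measured by Dijkstra on the 8-connected water lattice, and the distance
matrix is min-max normalized and subtracted from one.

Two stratification presets are provided: every 5 Myr to 45 Ma for
cetacean-aged trees, every 10 Myr to 140 Ma for the older groups, plus one deep stratum reaching 360 Ma
so the stack is older than any root age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .core import RealmSet
from .geo import haversine_km, spherical_centroid

__all__ = [
    "LatLonGrid",
    "PaleoSnapshot",
    "StratifiedDMM",
    "extrapolate_realms",
    "realm_centroids",
    "overwater_distance_matrix",
    "multipliers_from_distances",
    "build_stratified_dmm",
    "preset_boundaries",
    "write_dmm_stack",
    "read_dmm_stack",
]


@dataclass
class LatLonGrid:
    """Regular lon/lat lattice of cell centers with a boolean water mask."""

    lons: np.ndarray  # (nlon,) cell-center longitudes, degrees
    lats: np.ndarray  # (nlat,) cell-center latitudes, degrees
    water: np.ndarray  # (nlat, nlon) True where ocean
    wrap_lon: bool = False  # whether the grid spans all longitudes

    def __post_init__(self) -> None:
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.water = np.asarray(self.water, dtype=bool)
        if self.water.shape != (self.lats.size, self.lons.size):
            raise ValueError("water mask shape does not match lat/lon axes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.water.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        lon2, lat2 = np.meshgrid(self.lons, self.lats)
        return lon2, lat2


@dataclass
class PaleoSnapshot:
    """Rotated realm seed points plus the water mask at one epoch."""

    age: float  # Ma
    seed_lons: np.ndarray
    seed_lats: np.ndarray
    seed_realms: list[str]
    grid: LatLonGrid

    def __post_init__(self) -> None:
        self.seed_lons = np.asarray(self.seed_lons, dtype=float)
        self.seed_lats = np.asarray(self.seed_lats, dtype=float)
        if not (self.seed_lons.size == self.seed_lats.size == len(self.seed_realms)):
            raise ValueError("seed arrays and labels disagree in length")
        if self.seed_lons.size == 0:
            raise ValueError("snapshot has no seed points")


def extrapolate_realms(snapshot: PaleoSnapshot, realms: RealmSet) -> np.ndarray:
    """Label every water cell with the realm of its nearest seed point.

    Returns an (nlat, nlon) int array of realm indices, -1 on land.  Ties go
    to the seed of lower canonical realm order.  Realms with no seed at this
    epoch are simply absent from the labeling.
    """
    grid = snapshot.grid
    lon2, lat2 = grid.cell_centers()
    water_lon = lon2[grid.water]
    water_lat = lat2[grid.water]

    order = np.argsort([realms.index(r) for r in snapshot.seed_realms], kind="stable")
    seed_lons = snapshot.seed_lons[order]
    seed_lats = snapshot.seed_lats[order]
    seed_idx = np.array([realms.index(snapshot.seed_realms[i]) for i in order])

    dists = haversine_km(
        water_lon[:, None], water_lat[:, None], seed_lons[None, :], seed_lats[None, :]
    )
    nearest = np.argmin(dists, axis=1)  # first minimum -> lowest realm order

    labels = np.full(grid.shape, -1, dtype=int)
    labels[grid.water] = seed_idx[nearest]
    return labels


def realm_centroids(
    labels: np.ndarray, grid: LatLonGrid, realms: RealmSet
) -> dict[str, tuple[float, float]]:
    """Spherical-mean centroid of each labeled realm's cells."""
    lon2, lat2 = grid.cell_centers()
    centroids: dict[str, tuple[float, float]] = {}
    for i, lab in enumerate(realms.labels):
        mask = labels == i
        if not mask.any():
            continue
        centroids[lab] = spherical_centroid(lon2[mask], lat2[mask])
    return centroids


def _water_graph(grid: LatLonGrid):
    """Sparse 8-connected graph over water cells with great-circle weights."""
    nlat, nlon = grid.shape
    idx = np.full(grid.shape, -1, dtype=int)
    wy, wx = np.nonzero(grid.water)
    idx[wy, wx] = np.arange(wy.size)
    lon2, lat2 = grid.cell_centers()

    rows, cols, weights = [], [], []
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for dy, dx in offsets:
        ny = wy + dy
        nx = wx + dx
        ok = (ny >= 0) & (ny < nlat)
        if grid.wrap_lon:
            nx = nx % nlon
        else:
            ok &= (nx >= 0) & (nx < nlon)
        sy, sx = wy[ok], wx[ok]
        ty, tx = ny[ok], nx[ok]
        wet = grid.water[ty, tx]
        sy, sx, ty, tx = sy[wet], sx[wet], ty[wet], tx[wet]
        rows.append(idx[sy, sx])
        cols.append(idx[ty, tx])
        weights.append(haversine_km(lon2[sy, sx], lat2[sy, sx], lon2[ty, tx], lat2[ty, tx]))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    weights = np.concatenate(weights)
    graph = coo_matrix((weights, (rows, cols)), shape=(wy.size, wy.size)).tocsr()
    return graph, idx, wy, wx, lon2, lat2


def overwater_distance_matrix(
    centroids: dict[str, tuple[float, float]], grid: LatLonGrid, realms: RealmSet
) -> np.ndarray:
    """Pairwise shortest over-water path lengths (km) between realm centroids.

    Centroids snap to the nearest water cell; unreachable pairs come back
    as +inf with a warning.  Realms missing from ``centroids`` get an all-NaN
    row/column.
    """
    graph, idx, wy, wx, lon2, lat2 = _water_graph(grid)
    water_lon = lon2[wy, wx]
    water_lat = lat2[wy, wx]

    present = [lab for lab in realms.labels if lab in centroids]
    sources = []
    for lab in present:
        lon, lat = centroids[lab]
        sources.append(int(np.argmin(haversine_km(water_lon, water_lat, lon, lat))))

    dist = dijkstra(graph, directed=False, indices=sources)
    n = realms.count
    D = np.full((n, n), np.nan)
    for a, lab_a in enumerate(present):
        ia = realms.index(lab_a)
        D[ia, ia] = 0.0
        for b, lab_b in enumerate(present):
            D[realms.index(lab_a), realms.index(lab_b)] = dist[a, sources[b]]
    # enforce exact symmetry (Dijkstra is symmetric up to float noise here)
    D = np.where(np.isnan(D), np.nan, (D + D.T) / 2.0)
    if np.isinf(D).any():
        warnings.warn("some realm pairs are not connected over water (infinite distance)")
    return D


def multipliers_from_distances(
    D: np.ndarray,
    infinite_factor: float = 1.5,
    degenerate_to_ones: bool = True,
    floor: float = 0.0,
    norm_max: float | None = None,
) -> np.ndarray:
    """Min-max normalize distances and subtract from one: M = 1 - D/max(D).

    Infinite entries are first replaced by ``infinite_factor`` times the
    largest finite distance so unreachable pairs get a near-zero multiplier.
    When every off-diagonal distance is equal the matrix carries no contrast;
    the default returns all ones (no information, no penalty), switchable via
    ``degenerate_to_ones``.  ``norm_max`` overrides the normalizing maximum
    (used for global-across-epochs normalization); ``floor`` lifts
    off-diagonal zeros to a small epsilon.
    """
    D = np.asarray(D, dtype=float).copy()
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite_off = D[off][np.isfinite(D[off])]
    if np.isinf(D).any():
        if finite_off.size == 0:
            raise ValueError("all off-diagonal distances are infinite")
        D[np.isinf(D)] = infinite_factor * finite_off.max()
    valid = off & ~np.isnan(D)
    if not valid.any() or np.nanmax(D[valid]) == 0:
        M = np.ones_like(D)
    elif degenerate_to_ones and np.allclose(D[valid], D[valid].flat[0]):
        warnings.warn("all off-diagonal distances equal: returning all-ones multipliers")
        M = np.ones_like(D)
    else:
        dmax = norm_max if norm_max is not None else float(np.nanmax(D[valid]))
        M = 1.0 - D / dmax
        M = np.clip(M, 0.0, 1.0)
    if floor > 0:
        M[off & (M < floor)] = floor
    np.fill_diagonal(M, 1.0)
    M[np.isnan(D)] = np.nan
    return M


def preset_boundaries(group: str) -> np.ndarray:
    """Stratum upper boundaries (Ma) for a group preset.

    ``cetacean``: 5-Myr strata to 45 Ma plus a 45-360 Ma cap (10 intervals);
    ``other`` (seagrasses, corals, fishes): 10-Myr strata to 140 Ma plus a
    140-360 Ma cap (15 intervals).
    """
    if group == "cetacean":
        return np.array([*np.arange(5.0, 45.1, 5.0), 360.0])
    if group == "other":
        return np.array([*np.arange(10.0, 140.1, 10.0), 360.0])
    raise ValueError(f"unknown group preset {group!r}")


@dataclass
class StratifiedDMM:
    """Per-epoch multiplier (and optional distance) matrices with boundaries.

    ``boundaries`` are interval upper edges in Ma, strictly increasing; the
    i-th matrix applies on [boundaries[i-1], boundaries[i]) with an implicit
    lower edge of 0 for the first interval.
    """

    realms: RealmSet
    boundaries: np.ndarray
    matrices: list[np.ndarray]
    distances: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("epoch boundaries must be strictly increasing")
        if len(self.matrices) != self.boundaries.size:
            raise ValueError("need one multiplier matrix per interval")
        n = self.realms.count
        for M in self.matrices:
            if M.shape != (n, n):
                raise ValueError("multiplier matrix has wrong shape")
            finite = ~np.isnan(M)
            if np.any((M[finite] < -1e-12) | (M[finite] > 1 + 1e-12)):
                raise ValueError("multipliers must lie in [0, 1]")
            if not np.allclose(M, M.T, equal_nan=True):
                raise ValueError("multiplier matrix must be symmetric")
            if not np.allclose(np.diag(M)[~np.isnan(np.diag(M))], 1.0):
                raise ValueError("multiplier diagonal must be 1")

    @property
    def n_epochs(self) -> int:
        return len(self.matrices)

    def epoch_index(self, age: float) -> int:
        """Index of the stratum containing ``age`` (boundary ages go older)."""
        if age < 0:
            raise ValueError("age must be >= 0")
        i = int(np.searchsorted(self.boundaries, age, side="right"))
        return min(i, self.n_epochs - 1)

    def matrix_at(self, age: float) -> np.ndarray:
        return self.matrices[self.epoch_index(age)]

    def validate_root_age(self, root_age: float) -> None:
        if self.boundaries[-1] < root_age:
            raise ValueError(
                f"final boundary {self.boundaries[-1]} Ma is younger than the root age {root_age} Ma"
            )

    @classmethod
    def uniform(cls, realms: RealmSet, boundaries=(360.0,)) -> "StratifiedDMM":
        """All-ones multipliers (no geographic structure) for each stratum."""
        n = realms.count
        bounds = np.asarray(boundaries, dtype=float)
        return cls(realms, bounds, [np.ones((n, n)) for _ in bounds])


def build_stratified_dmm(
    snapshots: list[PaleoSnapshot],
    realms: RealmSet,
    boundaries: np.ndarray | None = None,
    group: str | None = None,
    normalize: str = "per-epoch",
    floor: float = 0.0,
) -> StratifiedDMM:
    """Run the full per-stratum pipeline and assemble the stratified stack.

    Snapshots are matched to intervals in order (youngest first), one per
    interval.  ``normalize`` is ``per-epoch`` (each stratum scaled by its own
    maximum distance) or ``global`` (one maximum across all strata).
    """
    if boundaries is None:
        if group is None:
            raise ValueError("give either explicit boundaries or a group preset")
        boundaries = preset_boundaries(group)
    boundaries = np.asarray(boundaries, dtype=float)
    if len(snapshots) != boundaries.size:
        raise ValueError(
            f"need one snapshot per interval: {boundaries.size} intervals, {len(snapshots)} snapshots"
        )
    snapshots = sorted(snapshots, key=lambda s: s.age)

    distance_mats = []
    for snap in snapshots:
        labels = extrapolate_realms(snap, realms)
        cents = realm_centroids(labels, snap.grid, realms)
        distance_mats.append(overwater_distance_matrix(cents, snap.grid, realms))

    norm_max = None
    if normalize == "global":
        finite = [D[np.isfinite(D)] for D in distance_mats]
        norm_max = max(float(f.max()) for f in finite if f.size)
    elif normalize != "per-epoch":
        raise ValueError("normalize must be 'per-epoch' or 'global'")

    matrices = [
        multipliers_from_distances(D, floor=floor, norm_max=norm_max) for D in distance_mats
    ]
    return StratifiedDMM(realms, boundaries, matrices, distances=distance_mats)


# -- text stack format -------------------------------------------------------

def write_dmm_stack(path, dmm: StratifiedDMM) -> None:
    """Write ``EPOCH <start> <end>`` headers each followed by an NxN matrix."""
    with open(path, "w") as fh:
        start = 0.0
        for end, M in zip(dmm.boundaries, dmm.matrices):
            fh.write(f"EPOCH {start:g} {end:g}\n")
            for row in M:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            start = end


def read_dmm_stack(path, realms: RealmSet) -> StratifiedDMM:
    boundaries: list[float] = []
    matrices: list[np.ndarray] = []
    n = realms.count
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith("EPOCH"):
            raise ValueError(f"expected EPOCH header, got {lines[i]!r}")
        _, _, end = lines[i].split()
        boundaries.append(float(end))
        rows = [np.fromstring(lines[i + 1 + k], sep=" ") for k in range(n)]
        matrices.append(np.vstack(rows))
        i += 1 + n
    return StratifiedDMM(realms, np.asarray(boundaries), matrices)
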