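"""Biotic and geographic predictor variables per realm.

Biotic: Faith's phylogenetic diversity (PD), Rosauer phylogenetic endemism
(PE; each branch's length divided by the number of realms its descendant
species jointly occupy), weighted endemism (WE; sum of 1/range-size over a
realm's species), fair-proportion evolutionary distinctiveness (ED;
summarized per realm by the median and standard deviation over member
species), and mean species range size.  Geographic: centroid isolation
(great-circle by default, chord optionally), continental shelf area
(0-200 m depth band) and realm area.  A pairwise-correlation screen at
|r| > 0.7 selects the final variable set deterministically.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Phylogeny, RangeState, RealmSet
from .geo import chord_km, haversine_km

__all__ = [
    "phylo_metrics",
    "evolutionary_distinctiveness",
    "mean_range_size",
    "euclidean_isolation",
    "shelf_area",
    "realm_area",
    "collinearity_screen",
    "predictor_table",
]


def _branch_realm_unions(tree: Phylogeny, assignments: Mapping[str, RangeState]):
    """Per non-root node: (branch length, descendant-tip count, realm union bits)."""
    union: dict[int, int] = {}
    n_desc: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            union[node.index] = assignments[node.label].bits
            n_desc[node.index] = 1
        else:
            bits = 0
            total = 0
            for child in node.children:
                bits |= union[child.index]
                total += n_desc[child.index]
            union[node.index] = bits
            n_desc[node.index] = total
    return union, n_desc


def phylo_metrics(
    tree: Phylogeny, assignments: Mapping[str, RangeState], realms: RealmSet
) -> pd.DataFrame:
    """PD, PE, WE and ED summaries per realm.

    Branch realm membership follows the union of its descendant species'
    realms; a branch contributes its full length to PD and length/(number of
    realms in the union) to PE of every realm in the union.  Realms with no
    species come back as NaN rows.
    """
    missing = set(tree.tip_labels) - set(assignments)
    if missing:
        raise ValueError(f"tips without assignments: {sorted(missing)[:5]}")
    union, _ = _branch_realm_unions(tree, assignments)
    ed = evolutionary_distinctiveness(tree)

    n = realms.count
    pd_vals = np.zeros(n)
    pe_vals = np.zeros(n)
    for node in tree.postorder():
        if node is tree.root:
            continue
        bits = union[node.index]
        k = bits.bit_count()
        if k == 0:
            continue
        for r in range(n):
            if bits >> r & 1:
                pd_vals[r] += node.length
                pe_vals[r] += node.length / k

    rows = []
    for r, lab in enumerate(realms.labels):
        members = [sp for sp, st in assignments.items() if r in st]
        if not members:
            rows.append(dict(realm=lab, PD=np.nan, PE=np.nan, WE=np.nan,
                             ED_median=np.nan, ED_sd=np.nan))
            continue
        we = sum(1.0 / assignments[sp].size for sp in members)
        eds = np.array([ed[sp] for sp in members if sp in ed])
        rows.append(
            dict(
                realm=lab,
                PD=pd_vals[r],
                PE=pe_vals[r],
                WE=we,
                ED_median=float(np.median(eds)),
                ED_sd=float(np.std(eds, ddof=1)) if eds.size > 1 else np.nan,
            )
        )
    return pd.DataFrame(rows).set_index("realm")


def evolutionary_distinctiveness(tree: Phylogeny) -> dict[str, float]:
    """Fair-proportion ED: each branch's length split equally among its tips."""
    _, n_desc = _branch_realm_unions(
        tree, {t: RangeState(1, 1) for t in tree.tip_labels}
    )
    ed = {t: 0.0 for t in tree.tip_labels}
    stack = [(tree.root, 0.0)]
    while stack:
        node, acc = stack.pop()
        if node.is_leaf:
            ed[node.label] = acc
            continue
        for child in node.children:
            stack.append((child, acc + child.length / n_desc[child.index]))
    return ed


def mean_range_size(
    assignments: Mapping[str, RangeState], realms: RealmSet
) -> pd.Series:
    """Mean range size (number of realms) of the species present per realm."""
    out = {}
    for r, lab in enumerate(realms.labels):
        sizes = [st.size for st in assignments.values() if r in st]
        out[lab] = float(np.mean(sizes)) if sizes else np.nan
    return pd.Series(out)


def euclidean_isolation(
    centroids: Mapping[str, tuple[float, float]], method: str = "greatcircle"
) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise centroid distances (km) and per-realm mean distance to others."""
    fn = {"greatcircle": haversine_km, "chord": chord_km}.get(method)
    if fn is None:
        raise ValueError("method must be 'greatcircle' or 'chord'")
    labels = list(centroids)
    lons = np.array([centroids[lab][0] for lab in labels])
    lats = np.array([centroids[lab][1] for lab in labels])
    D = fn(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    np.fill_diagonal(D, 0.0)
    Ddf = pd.DataFrame(D, index=labels, columns=labels)
    iso = pd.Series(
        {lab: D[i, np.arange(len(labels)) != i].mean() for i, lab in enumerate(labels)}
    )
    return Ddf, iso


def shelf_area(
    depths: np.ndarray,
    realm_labels: np.ndarray,
    cell_area_km2: np.ndarray | float,
    realms: RealmSet,
) -> pd.Series:
    """Total area of cells in the 0-200 m depth band per realm.

    ``depths`` holds elevations in meters (negative below sea level); a cell
    counts when -200 <= depth < 0 (the 200 m boundary is included).  NaN
    depths are excluded.
    """
    depths = np.asarray(depths, dtype=float)
    realm_labels = np.asarray(realm_labels)
    areas = np.broadcast_to(np.asarray(cell_area_km2, dtype=float), depths.shape)
    with np.errstate(invalid="ignore"):
        shelf = (depths >= -200.0) & (depths < 0.0)
    out = {}
    for r, lab in enumerate(realms.labels):
        mask = shelf & (realm_labels == r)
        out[lab] = float(areas[mask].sum())
    return pd.Series(out)


def realm_area(
    realm_labels: np.ndarray, cell_area_km2: np.ndarray | float, realms: RealmSet
) -> pd.Series:
    realm_labels = np.asarray(realm_labels)
    areas = np.broadcast_to(np.asarray(cell_area_km2, dtype=float), realm_labels.shape)
    return pd.Series(
        {lab: float(areas[realm_labels == r].sum()) for r, lab in enumerate(realms.labels)}
    )


def collinearity_screen(table: pd.DataFrame, threshold: float = 0.7) -> list[str]:
    """Iterative pairwise-correlation elimination at |r| > ``threshold``.

    Constant columns are dropped first (with a warning).  While some pair of
    retained variables exceeds the threshold, the member of the worst pair
    with the larger mean |r| against all other retained variables is removed
    (ties go to the later column), giving a deterministic retained set.
    """
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("need at least 2 variables over at least 3 realms")
    retained = []
    for c in table.columns:
        if np.nanstd(table[c].to_numpy(dtype=float)) == 0:
            warnings.warn(f"constant predictor {c!r} dropped before screening")
        else:
            retained.append(c)
    while len(retained) > 1:
        corr = table[retained].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= threshold:
            break
        mean_i = corr[i, :].sum() / (len(retained) - 1)
        mean_j = corr[j, :].sum() / (len(retained) - 1)
        drop = max(i, j) if np.isclose(mean_i, mean_j) else (i if mean_i > mean_j else j)
        retained.pop(drop)
    return retained


def predictor_table(
    tree: Phylogeny,
    assignments: Mapping[str, RangeState],
    realms: RealmSet,
    centroids: Mapping[str, tuple[float, float]] | None = None,
    depths: np.ndarray | None = None,
    realm_labels: np.ndarray | None = None,
    cell_area_km2: np.ndarray | float = 1.0,
    body_size_cm: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Assemble the realm x variable predictor matrix."""
    out = phylo_metrics(tree, assignments, realms)
    out["mean_range_size"] = mean_range_size(assignments, realms)
    if centroids is not None:
        _, iso = euclidean_isolation(centroids)
        out["isolation_km"] = iso
    if depths is not None and realm_labels is not None:
        out["shelf_area_km2"] = shelf_area(depths, realm_labels, cell_area_km2, realms)
        out["realm_area_km2"] = realm_area(realm_labels, cell_area_km2, realms)
    if body_size_cm is not None:
        sizes = {}
        for r, lab in enumerate(realms.labels):
            vals = [body_size_cm[sp] for sp, st in assignments.items()
                    if r in st and sp in body_size_cm]
            sizes[lab] = float(np.mean(vals)) if vals else np.nan
        out["body_size_cm"] = pd.Series(sizes)
    return out
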