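"""Aggregation of stochastic-map event logs into summary products.

The downstream products are the pipeline's reporting layer: per-realm event
tables (mean over maps, summed over clades), realm-to-realm interchange
matrices with source/sink percentages, global process shares, richness
standardization with a minimum-richness exclusion rule, rolling binned time
series, and per-realm lineages-through-time curves with quantile envelopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CladeDataset, RealmSet
from .bsm import (
    ALLOPATRY,
    DISPERSAL,
    EVENT_TYPES,
    EXTINCTION,
    FOUNDER_SPECIATION,
    IN_SITU,
    SUBSET,
    EventLog,
    EventRecord,
    classify_events,
)

__all__ = [
    "EventTable",
    "InterchangeMatrix",
    "TallyResult",
    "tally",
    "process_shares",
    "standardize_by_richness",
    "realm_share",
    "binned_series",
    "ltt_per_realm",
    "top_quantile_edges",
]

logger = logging.getLogger(__name__)

#: realm-level columns of the event table
REALM_COLUMNS = ("in_situ_speciation", "subset_sympatry", "allopatry",
                 "immigration", "emigration", "extinction")


@dataclass
class EventTable:
    """Realm x event-type tallies: mean over maps with spread summaries."""

    mean: pd.DataFrame
    median: pd.DataFrame
    q025: pd.DataFrame
    q975: pd.DataFrame
    per_map: np.ndarray  # (n_maps, n_realms, n_columns)


@dataclass
class InterchangeMatrix:
    """Realm x realm dispersal counts (source rows, sink columns).

    Off-diagonal entries are mean dispersal + founder counts after source
    attribution; the diagonal's information (in-situ and extinction counts)
    is kept in separate series.
    """

    matrix: pd.DataFrame
    in_situ: pd.Series
    extinction: pd.Series

    @property
    def source_totals(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    @property
    def sink_totals(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.matrix.values.sum())

    def source_percentages(self) -> pd.Series:
        return 100.0 * self.source_totals / self.grand_total

    def sink_percentages(self) -> pd.Series:
        return 100.0 * self.sink_totals / self.grand_total


@dataclass
class TallyResult:
    table: EventTable
    interchange: InterchangeMatrix
    process_totals: pd.Series  # mean over maps of global per-type counts
    process_per_map: pd.DataFrame


def _realm_counts(records: Sequence[EventRecord], n_realms: int) -> np.ndarray:
    """Realm x REALM_COLUMNS count matrix for one map's records."""
    counts = np.zeros((n_realms, len(REALM_COLUMNS)))
    col = {c: i for i, c in enumerate(REALM_COLUMNS)}
    for ev in records:
        if ev.etype in (DISPERSAL, FOUNDER_SPECIATION):
            counts[ev.dest, col["immigration"]] += 1.0
            for realm, w in ev.source:
                counts[realm, col["emigration"]] += w
        elif ev.etype == EXTINCTION:
            counts[ev.realms[0], col["extinction"]] += 1.0
        elif ev.etype == IN_SITU:
            for realm, w in ev.source:
                counts[realm, col["in_situ_speciation"]] += w
        elif ev.etype == SUBSET:
            counts[ev.realms[0], col["subset_sympatry"]] += 1.0
        elif ev.etype == ALLOPATRY:
            for realm, w in ev.source:
                counts[realm, col["allopatry"]] += w
    return counts


def _interchange_counts(records: Sequence[EventRecord], n_realms: int) -> np.ndarray:
    counts = np.zeros((n_realms, n_realms))
    for ev in records:
        if ev.etype in (DISPERSAL, FOUNDER_SPECIATION):
            for realm, w in ev.source:
                counts[realm, ev.dest] += w
    return counts


def _type_counts(records: Sequence[EventRecord]) -> np.ndarray:
    counts = np.zeros(len(EVENT_TYPES))
    idx = {t: i for i, t in enumerate(EVENT_TYPES)}
    for ev in records:
        counts[idx[ev.etype]] += 1.0
    return counts


def tally(
    logs_by_clade: Sequence[Sequence[EventLog]], realms: RealmSet
) -> TallyResult:
    """Aggregate classified event logs across maps and clades.

    ``logs_by_clade`` holds, per clade, its list of stochastic maps (equal
    length across clades; maps are paired by replicate index).  Counts are
    summed over clades and summarized over maps by mean, median and the
    2.5/97.5% quantiles.
    """
    if logs_by_clade and isinstance(logs_by_clade[0], EventLog):
        logs_by_clade = [logs_by_clade]  # single clade given flat
    if not logs_by_clade or not logs_by_clade[0]:
        raise ValueError("no event logs to tally")
    n_maps = len(logs_by_clade[0])
    if any(len(logs) != n_maps for logs in logs_by_clade):
        raise ValueError("every clade must contribute the same number of maps")
    n = realms.count

    realm_mats = np.zeros((n_maps, n, len(REALM_COLUMNS)))
    inter_mats = np.zeros((n_maps, n, n))
    type_mats = np.zeros((n_maps, len(EVENT_TYPES)))
    for logs in logs_by_clade:
        for m, log in enumerate(logs):
            records = classify_events(log)
            realm_mats[m] += _realm_counts(records, n)
            inter_mats[m] += _interchange_counts(records, n)
            type_mats[m] += _type_counts(records)

    def frame(arr2d: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(arr2d, index=list(realms.labels), columns=list(REALM_COLUMNS))

    table = EventTable(
        mean=frame(realm_mats.mean(axis=0)),
        median=frame(np.median(realm_mats, axis=0)),
        q025=frame(np.quantile(realm_mats, 0.025, axis=0)),
        q975=frame(np.quantile(realm_mats, 0.975, axis=0)),
        per_map=realm_mats,
    )
    inter_mean = inter_mats.mean(axis=0)
    np.fill_diagonal(inter_mean, 0.0)
    interchange = InterchangeMatrix(
        matrix=pd.DataFrame(inter_mean, index=list(realms.labels), columns=list(realms.labels)),
        in_situ=table.mean["in_situ_speciation"],
        extinction=table.mean["extinction"],
    )
    process_per_map = pd.DataFrame(type_mats, columns=list(EVENT_TYPES))
    return TallyResult(
        table=table,
        interchange=interchange,
        process_totals=process_per_map.mean(axis=0),
        process_per_map=process_per_map,
    )


def process_shares(totals: Mapping[str, float] | pd.Series) -> pd.Series:
    """Percentage of the grand total contributed by each process type."""
    s = pd.Series(totals, dtype=float)
    if (s < 0).any():
        raise ValueError("totals must be >= 0")
    grand = s.sum()
    if grand == 0:
        raise ValueError("all process totals are zero")
    return 100.0 * s / grand


def standardize_by_richness(
    table: pd.DataFrame,
    richness: Mapping[str, int],
    scale: float = 1.0,
    min_richness: int = 2,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-species event rates: value / realm richness, times ``scale``.

    Realms with fewer than ``min_richness`` extant species (by default 1 or
    fewer, too few to carry a rate) come back as NaN and are listed in the
    second return value.
    """
    out = table.astype(float).copy()
    excluded = []
    for realm in table.index:
        r = richness.get(realm, 0)
        if r < min_richness:
            out.loc[realm] = np.nan
            excluded.append(realm)
        else:
            out.loc[realm] = table.loc[realm] * scale / r
    return out, excluded


def realm_share(
    values: Mapping[str, float] | pd.Series, exclude: Sequence[str] = ()
) -> pd.Series:
    """Each realm's percentage of the summed (included) standardized values."""
    s = pd.Series(values, dtype=float).drop(index=list(exclude), errors="ignore").dropna()
    if s.empty:
        raise ValueError("no realms left after exclusions")
    return 100.0 * s / s.sum()


def binned_series(
    records_by_map: Sequence[Sequence[EventRecord]],
    realms: RealmSet,
    bin_width: float = 1.0,
    window: int = 3,
    span: float = 65.0,
    richness: Mapping[str, int] | None = None,
    scale: float = 1.0,
) -> dict[tuple[str, str], np.ndarray]:
    """Rolling-mean event counts per realm and type over the past ``span`` Myr.

    Events are binned per ``bin_width`` Myr (youngest bin first), averaged
    over maps, smoothed with a centered ``window``-bin rolling mean (partial
    windows average over the available bins), and optionally standardized by
    realm richness after binning.  Events older than ``span`` are dropped
    (logged).
    """
    if records_by_map and isinstance(records_by_map[0], EventRecord):
        records_by_map = [records_by_map]
    n_bins = int(np.ceil(span / bin_width))
    n = realms.count
    acc = np.zeros((len(records_by_map), n, len(REALM_COLUMNS), n_bins))
    dropped = 0
    col = {c: i for i, c in enumerate(REALM_COLUMNS)}
    for m, records in enumerate(records_by_map):
        for ev in records:
            if ev.time >= span:
                dropped += 1
                continue
            b = int(ev.time // bin_width)
            if ev.etype in (DISPERSAL, FOUNDER_SPECIATION):
                acc[m, ev.dest, col["immigration"], b] += 1.0
                for realm, w in ev.source:
                    acc[m, realm, col["emigration"], b] += w
            elif ev.etype == EXTINCTION:
                acc[m, ev.realms[0], col["extinction"], b] += 1.0
            elif ev.etype == IN_SITU:
                for realm, w in ev.source:
                    acc[m, realm, col["in_situ_speciation"], b] += w
            elif ev.etype == SUBSET:
                acc[m, ev.realms[0], col["subset_sympatry"], b] += 1.0
            elif ev.etype == ALLOPATRY:
                for realm, w in ev.source:
                    acc[m, realm, col["allopatry"], b] += w
    if dropped:
        logger.info("binned_series: dropped %d events older than %g Ma", dropped, span)
    mean = acc.mean(axis=0)

    out: dict[tuple[str, str], np.ndarray] = {}
    for ri, realm in enumerate(realms.labels):
        factor = 1.0
        if richness is not None:
            r = richness.get(realm, 0)
            factor = np.nan if r < 2 else scale / r
        for ctype, ci in col.items():
            series = pd.Series(mean[ri, ci])
            rolled = series.rolling(window, center=True, min_periods=1).mean().to_numpy()
            out[(realm, ctype)] = rolled * factor
    return out


def ltt_per_realm(
    logs: Sequence[EventLog],
    clade: CladeDataset,
    realms: RealmSet,
    bin_width: float = 0.1,
) -> dict[str, pd.DataFrame]:
    """Lineages occupying each realm per timebin, with quantile envelopes.

    Each sampled history is replayed to recover every branch's range state
    through time; a lineage counts toward a realm in a bin when its range at
    the bin midpoint includes the realm.  Above the root age the single root
    lineage is counted in its realm(s).  Returns per realm a frame with the
    mean and the 2.5/97.5% quantiles across maps.
    """
    tree = clade.tree
    root_age = tree.root_age
    n_bins = max(int(np.ceil(root_age / bin_width)), 1)
    mids = (np.arange(n_bins) + 0.5) * bin_width
    n = realms.count
    counts = np.zeros((len(logs), n, n_bins))

    parent_age = {}
    node_by_index = {node.index: node for node in tree.postorder()}
    for node in tree.preorder():
        for child in node.children:
            parent_age[child.index] = node.age

    for m, log in enumerate(logs):
        by_branch: dict[int, list] = {}
        for ev in log.anagenetic:
            by_branch.setdefault(ev.branch_id, []).append(ev)
        for branch_id, (top, bottom) in log.branch_states.items():
            t_hi = parent_age[branch_id]
            t_lo = node_by_index[branch_id].age
            events = sorted(by_branch.get(branch_id, []), key=lambda e: -e.time)
            # step through bins covered by this branch, oldest first
            in_bins = np.nonzero((mids >= t_lo) & (mids < t_hi))[0]
            state = top
            ei = 0
            for b in reversed(in_bins):  # oldest bin first
                t = mids[b]
                while ei < len(events) and events[ei].time > t:
                    state = events[ei].to_bits
                    ei += 1
                for r in range(n):
                    if state >> r & 1:
                        counts[m, r, b] += 1.0
        # the root lineage above the root node
        root_state = log.node_states[tree.root.index]
        above = np.nonzero(mids >= root_age)[0]
        for r in range(n):
            if root_state >> r & 1:
                counts[m, r, above] += 1.0

    out = {}
    for ri, realm in enumerate(realms.labels):
        out[realm] = pd.DataFrame(
            {
                "age": mids,
                "mean": counts[:, ri, :].mean(axis=0),
                "q025": np.quantile(counts[:, ri, :], 0.025, axis=0),
                "q975": np.quantile(counts[:, ri, :], 0.975, axis=0),
            }
        )
    return out


def top_quantile_edges(
    interchange: pd.DataFrame | InterchangeMatrix, q: float = 0.25
) -> list[tuple[str, str, float]]:
    """Directed source->sink edges in the top ``q`` fraction by weight.

    The threshold is the (1-q) quantile (linear interpolation) of the
    positive off-diagonal weights; ties at the threshold are kept.
    """
    if isinstance(interchange, InterchangeMatrix):
        interchange = interchange.matrix
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    values = interchange.values.copy().astype(float)
    np.fill_diagonal(values, 0.0)
    positive = values[values > 0]
    if positive.size == 0:
        return []
    threshold = float(np.quantile(positive, 1.0 - q))
    edges = []
    labels = list(interchange.index)
    for i, src in enumerate(labels):
        for j, dst in enumerate(labels):
            if i != j and values[i, j] > 0 and values[i, j] >= threshold:
                edges.append((src, dst, float(values[i, j])))
    edges.sort(key=lambda e: -e[2])
    return edges
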