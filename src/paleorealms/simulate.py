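"""Synthetic data: birth-death clades, forward range evolution, drifting
paleogeographies and full benchmark bundles.

The forward range simulator reuses the same rate-matrix and cladogenetic
event-table builders as the likelihood machinery, so simulator and
inference share one definition of the process, and every simulated event is
logged in the same EventLog structure the stochastic maps use — ground
truth flows through the identical accounting code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CladeDataset, ModelParams, Node, Phylogeny, RangeState, RealmSet
from .dmm import LatLonGrid, PaleoSnapshot, StratifiedDMM, preset_boundaries
from .models import StateSpace, _branch_segments, _Engine, build_clado_table, build_Q
from .bsm import AnageneticEvent, CladogeneticEvent, EventLog, _PathSampler, _sample_once

__all__ = [
    "SimConfig",
    "sim_tree",
    "sim_ranges",
    "sim_ranges_conditional",
    "sim_paleogeography",
    "Bundle",
    "make_benchmark_bundle",
]


@dataclass
class SimConfig:
    """Study-condition defaults for one simulated clade.

    Clades span the 10-100 tip window the pipeline targets; birth/death rates
    give moderately old clades, and the generating model parameters sit in
    the range the DEC-family fits explore.
    """

    seed: int = 0
    n_tips: int = 30
    birth: float = 0.15  # /Myr
    death: float = 0.05  # /Myr
    n_realms: int = 5
    model: str = "DEC"
    params: ModelParams = field(default_factory=lambda: ModelParams(d=0.1, e=0.03))
    group: str = "other"  # stratification preset: 'cetacean' or 'other'
    max_range_size: int | None = None

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("need at least 2 tips")
        if not self.birth > self.death >= 0:
            raise ValueError("need birth > death >= 0")


def sim_tree(config: SimConfig, max_restarts: int = 1000) -> Phylogeny:
    """Forward birth-death tree conditioned on the number of extant tips.

    Simulation starts at the root split with two lineages; on reaching
    ``n_tips`` extant lineages the clock runs one further exponential
    waiting time before stopping, so for a pure-birth process the expected
    root age is sum_{k=2..n} 1/(lambda k).  Extinct subtrees are pruned
    (which can shift the crown downward); full extinction restarts.
    """
    rng = np.random.default_rng(config.seed)
    lam, mu, n = config.birth, config.death, config.n_tips
    for _ in range(max_restarts):
        # each lineage: [start_time, parent_record_index, end_time, fate]
        records: list[list] = [[0.0, -1, None, None], [0.0, -1, None, None]]
        active = [0, 1]
        t = 0.0
        failed = False
        while len(active) < n:
            total = (lam + mu) * len(active)
            t += rng.exponential(1.0 / total)
            i = active[rng.integers(len(active))]
            if rng.uniform() < lam / (lam + mu):
                records[i][2], records[i][3] = t, "split"
                for _child in range(2):
                    records.append([t, i, None, None])
                    active.append(len(records) - 1)
                active.remove(i)
            else:
                records[i][2], records[i][3] = t, "dead"
                active.remove(i)
                if not active:
                    failed = True
                    break
        if failed:
            continue
        t += rng.exponential(1.0 / ((lam + mu) * len(active)))
        for i in active:
            records[i][2], records[i][3] = t, "extant"
        tree = _records_to_tree(records, t)
        if tree is not None and tree.n_tips == n:
            return tree
    raise RuntimeError("birth-death simulation failed: all lineages kept dying")


def _records_to_tree(records, T: float) -> Phylogeny | None:
    children: dict[int, list[int]] = {}
    for i, rec in enumerate(records):
        if rec[1] >= 0:
            children.setdefault(rec[1], []).append(i)

    counter = [0]

    def build(i: int) -> Node | None:
        start, _, end, fate = records[i]
        if fate == "dead":
            return None
        if fate == "extant":
            counter[0] += 1
            return Node(label=f"t{counter[0]}", length=end - start)
        kids = [build(c) for c in children.get(i, [])]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:  # suppress the unifurcation left by pruning
            kids[0].length += end - start
            return kids[0]
        node = Node(length=end - start)
        for k in kids:
            node.add_child(k)
        return node

    roots = [build(i) for i in (0, 1)]
    roots = [r for r in roots if r is not None]
    if not roots:
        return None
    if len(roots) == 1:
        root = roots[0]
        root.length = 0.0
        if root.is_leaf:
            return None
    else:
        root = Node()
        for r in roots:
            root.add_child(r)
    return Phylogeny(root)


def sim_ranges(
    tree: Phylogeny,
    dmm: StratifiedDMM,
    config: SimConfig,
    max_resamples: int = 100,
    resample_scope: str = "clade",
) -> tuple[dict[str, RangeState], EventLog]:
    """Forward-simulate range evolution with a full ground-truth event log.

    The root range is drawn from a flat prior over non-empty states;
    anagenetic events follow a Gillespie simulation of the epoch-dependent
    rate matrix, cladogenetic events are drawn from the model's event table
    at each node.  A lineage absorbed into the empty range is extinct in
    place; with ``resample_scope='clade'`` (the default) the whole clade is
    resampled when any tip ends empty, capped at ``max_resamples``.  On
    large trees some lineage almost surely dies, so the ``'branch'`` scope
    instead retries just the offending branch path — conditioning each
    branch on non-absorption, a local conditioning with a small downward
    bias on realized extirpation counts.
    """
    if resample_scope not in ("clade", "branch"):
        raise ValueError("resample_scope must be 'clade' or 'branch'")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    n = config.n_realms
    space = StateSpace(n, config.max_range_size)
    dmm.validate_root_age(tree.root_age)
    Qs = {e: build_Q(config.params, dmm.matrices[e], space) for e in range(dmm.n_epochs)}
    tables = {
        e: build_clado_table(config.model, config.params, space, dmm.matrices[e])
        for e in range(dmm.n_epochs)
    }

    for _attempt in range(max_resamples):
        log = EventLog(replicate=0, n_realms=n, node_states={}, branch_states={})
        state: dict[int, int] = {tree.root.index: int(rng.integers(1, len(space)))}
        ok = True
        for node in tree.preorder():
            a = state[node.index]
            if node.is_leaf:
                log.node_states[node.index] = space.states[a]
                if a == 0:
                    ok = False
                continue
            log.node_states[node.index] = space.states[a]
            if a == 0:
                ok = False
                # propagate emptiness so the resample check fires at the tips
                for child in node.children:
                    state[child.index] = 0
                    log.branch_states[child.index] = (0, 0)
                continue
            table = tables[dmm.epoch_index(node.age)]
            li, ri, types, probs = table.events[a]
            ei = int(rng.choice(probs.size, p=probs))
            log.cladogenetic.append(
                CladogeneticEvent(
                    node_id=node.index,
                    time=node.age,
                    ancestor_bits=space.states[a],
                    left_bits=space.states[li[ei]],
                    right_bits=space.states[ri[ei]],
                    etype=types[ei],
                )
            )
            for child, top in zip(node.children, (li[ei], ri[ei])):
                bottom = _gillespie_branch(
                    log, rng, Qs, dmm, space, child.index, child.age, node.age, int(top),
                    condition_on_survival=(resample_scope == "branch"),
                )
                state[child.index] = bottom
                log.branch_states[child.index] = (space.states[top], space.states[bottom])
        if ok:
            ranges = {
                t.label: RangeState(log.node_states[t.index], n) for t in tree.tips
            }
            return ranges, log
    raise RuntimeError(f"tip ranges kept going extinct after {max_resamples} resamples")


def sim_ranges_conditional(
    tree: Phylogeny,
    dmm: StratifiedDMM,
    config: SimConfig,
    max_retries: int = 1000,
) -> tuple[dict[str, RangeState], EventLog]:
    """Exact forward simulation conditioned on every tip range surviving.

    Draws one full history from the model conditioned on no tip having the
    empty range — the same distribution that clade-level
    resample-until-no-tip-empty targets, but sampled directly (constraint
    vectors at the tips plus endpoint-conditioned path sampling), so it
    stays feasible on trees where unconditional survival is vanishingly
    rare.  Fits on such data should use the survival-conditioned
    likelihood.
    """
    n = config.n_realms
    placeholder = {t.label: RangeState(1, n) for t in tree.tips}
    clade0 = CladeDataset(tree=tree, ranges=placeholder)
    engine = _Engine(clade0, dmm, config.model, config.params, config.max_range_size)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0DE]))
    nonempty = np.ones(len(engine.space))
    nonempty[0] = 0.0
    L, _ = engine.downpass(tip_vectors={t: nonempty for t in tree.tip_labels})
    if L is None:
        raise ValueError("survival probability vanished under these parameters")
    sampler = _PathSampler(engine, rng)
    for _attempt in range(max_retries):
        try:
            log = _sample_once(engine, sampler, rng, L, replicate=0)
        except RuntimeError:
            continue
        ranges = {
            t.label: RangeState(log.node_states[t.index], n) for t in tree.tips
        }
        return ranges, log
    raise RuntimeError(f"conditional simulation failed after {max_retries} retries")


def _gillespie_branch(
    log, rng, Qs, dmm, space, branch_id, t_bottom, t_top, a: int,
    condition_on_survival: bool = False, max_retries: int = 10_000,
) -> int:
    start = a
    for _attempt in range(max_retries if condition_on_survival else 1):
        a = start
        events: list[AnageneticEvent] = []
        segments = list(reversed(_branch_segments(t_bottom, t_top, dmm)))  # old -> young
        age = t_top
        for dt, epoch in segments:
            Q = Qs[epoch]
            u = 0.0
            while True:
                total = -Q[a, a]
                if total <= 0:
                    break
                u += rng.exponential(1.0 / total)
                if u >= dt:
                    break
                rates = Q[a].copy()
                rates[a] = 0.0
                b = int(rng.choice(rates.size, p=rates / rates.sum()))
                events.append(
                    AnageneticEvent(
                        branch_id=branch_id,
                        time=age - u,
                        from_bits=space.states[a],
                        to_bits=space.states[b],
                    )
                )
                a = b
            age -= dt
        if not condition_on_survival or a != 0:
            log.anagenetic.extend(events)
            return a
    raise RuntimeError("branch path kept hitting the empty range")


def sim_paleogeography(
    realms: RealmSet,
    boundaries: np.ndarray | None = None,
    group: str = "other",
    drift_deg_per_myr: float = 0.2,
    land_bars: list[tuple[float, float, float, float]] | None = None,
    grid_deg: float = 5.0,
    seed: int = 0,
) -> list[PaleoSnapshot]:
    """Per-epoch realm seed points on a drifting-ocean toy world.

    Each realm gets a seed track that drifts linearly in longitude with age;
    ``land_bars`` are (age_from, age_to, lon_min, lon_max) strips of land
    spanning all latitudes that exist in that age window (emulating, e.g.,
    a closing seaway).  One snapshot is produced per stratification
    interval, placed at the interval's lower (younger) edge.
    """
    if boundaries is None:
        boundaries = preset_boundaries(group)
    boundaries = np.asarray(boundaries, dtype=float)
    rng = np.random.default_rng(seed)
    lons = np.arange(-180 + grid_deg / 2, 180, grid_deg)
    lats = np.arange(-60 + grid_deg / 2, 60, grid_deg)
    base_lons = rng.uniform(-150, 150, size=realms.count)
    base_lats = rng.uniform(-40, 40, size=realms.count)
    velocities = rng.uniform(-drift_deg_per_myr, drift_deg_per_myr, size=realms.count)

    snapshots = []
    start = 0.0
    for end in boundaries:
        age = start
        water = np.ones((lats.size, lons.size), dtype=bool)
        for bar in land_bars or []:
            a0, a1, lo, hi = bar
            if a0 <= age < a1:
                water[:, (lons >= lo) & (lons <= hi)] = False
        seed_lons = ((base_lons + velocities * age + 180) % 360) - 180
        # keep seeds off any land bar by nudging east until wet
        for i in range(realms.count):
            tries = 0
            while tries < lons.size:
                j = int(np.argmin(np.abs(lons - seed_lons[i])))
                k = int(np.argmin(np.abs(lats - base_lats[i])))
                if water[k, j]:
                    break
                seed_lons[i] = ((seed_lons[i] + grid_deg + 180) % 360) - 180
                tries += 1
        snapshots.append(
            PaleoSnapshot(
                age=age,
                seed_lons=seed_lons,
                seed_lats=base_lats.copy(),
                seed_realms=list(realms.labels),
                grid=LatLonGrid(lons, lats, water, wrap_lon=True),
            )
        )
        start = end
    return snapshots


@dataclass
class Bundle:
    """A desk-scale analogue of the multi-group, multi-clade study design."""

    clades: list[CladeDataset]
    dmm: StratifiedDMM
    realms: RealmSet
    richness: dict[str, int]
    truth_logs: list[EventLog]
    config: SimConfig


def make_benchmark_bundle(
    group_preset: str = "other",
    seed: int = 0,
    n_groups: int = 4,
    clades_per_group: int = 5,
    tips_range: tuple[int, int] = (10, 50),
    n_realms: int = 5,
    model: str = "DEC",
    params: ModelParams | None = None,
) -> Bundle:
    """Simulate pseudo-groups of clades with known parameters end to end."""
    if params is None:
        params = ModelParams(d=0.1, e=0.03)
    realms = RealmSet(tuple(f"R{i}" for i in range(n_realms)))
    boundaries = preset_boundaries(group_preset)
    dmm = StratifiedDMM.uniform(realms, boundaries)
    rng = np.random.default_rng(seed)

    clades: list[CladeDataset] = []
    logs: list[EventLog] = []
    base_config = None
    for g in range(n_groups):
        for c in range(clades_per_group):
            cfg = SimConfig(
                seed=int(rng.integers(2**31)),
                n_tips=int(rng.integers(tips_range[0], tips_range[1] + 1)),
                n_realms=n_realms,
                model=model,
                params=params,
                group=group_preset,
            )
            base_config = base_config or cfg
            tree = sim_tree(cfg)
            ranges, log = sim_ranges(tree, dmm, cfg)
            clades.append(CladeDataset(tree=tree, ranges=ranges, group=f"group{g + 1}"))
            logs.append(log)

    richness = {lab: 0 for lab in realms.labels}
    for clade in clades:
        for st in clade.ranges.values():
            for i in st.indices():
                richness[realms.labels[i]] += 1
    return Bundle(
        clades=clades,
        dmm=dmm,
        realms=realms,
        richness=richness,
        truth_logs=logs,
        config=base_config,
    )
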