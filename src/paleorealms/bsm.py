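"""Biogeographic stochastic mapping.

A stochastic map is one full history of range states and events drawn from
the posterior of the fitted model conditional on the tip ranges: node states
are sampled from the downpass conditional likelihoods, a cladogenetic event
is drawn per node, and anagenetic paths along branches are sampled
conditional on both endpoints by uniformization.  Every sampled history
replays exactly to its branch endpoint states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CladeDataset, ModelParams
from .dmm import StratifiedDMM
from .models import (
    FOUNDER,
    NARROW_SYMPATRY,
    SUBSET_SYMPATRY,
    VICARIANCE,
    FitResult,
    _branch_segments,
    _Engine,
)

__all__ = [
    "AnageneticEvent",
    "CladogeneticEvent",
    "EventRecord",
    "EventLog",
    "sample_history",
    "run_bsm",
    "classify_events",
    "replay_is_consistent",
]

IN_SITU = "in_situ_speciation"
FOUNDER_SPECIATION = "founder_event_speciation"
ALLOPATRY = "allopatry"
SUBSET = "subset_sympatry"
DISPERSAL = "dispersal"
EXTINCTION = "extinction"

EVENT_TYPES = (IN_SITU, FOUNDER_SPECIATION, ALLOPATRY, SUBSET, DISPERSAL, EXTINCTION)


@dataclass(frozen=True)
class AnageneticEvent:
    """One range change along a branch (single-realm gain or loss)."""

    branch_id: int  # index of the node at the bottom of the branch
    time: float  # Ma
    from_bits: int
    to_bits: int


@dataclass(frozen=True)
class CladogeneticEvent:
    """Daughter-range assignment at one internal node."""

    node_id: int
    time: float  # node age, Ma
    ancestor_bits: int
    left_bits: int
    right_bits: int
    etype: str  # narrow_sympatry / subset_sympatry / vicariance / founder


@dataclass(frozen=True)
class EventRecord:
    """A typed, timed, realm-attributed biogeographic event."""

    etype: str
    time: float
    branch_id: int
    source: tuple[tuple[int, float], ...] = ()  # (realm index, weight)
    dest: int | None = None
    realms: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.etype!r}")
        if self.source:
            total = sum(w for _, w in self.source)
            if any(w < 0 for _, w in self.source) or abs(total - 1.0) > 1e-9:
                raise ValueError("source attribution weights must be >= 0 and sum to 1")


@dataclass
class EventLog:
    """All events of one stochastic map plus the sampled states."""

    replicate: int
    n_realms: int
    node_states: dict[int, int]  # node index -> ancestral (pre-clado) bits
    branch_states: dict[int, tuple[int, int]]  # child node index -> (top, bottom) bits
    anagenetic: list[AnageneticEvent] = field(default_factory=list)
    cladogenetic: list[CladogeneticEvent] = field(default_factory=list)


class _PathSampler:
    """Endpoint-conditioned CTMC path sampling by uniformization."""

    def __init__(self, engine: _Engine, rng: np.random.Generator, max_jumps: int = 10_000):
        self.engine = engine
        self.rng = rng
        self.max_jumps = max_jumps

    def sample_segment(self, epoch: int, T: float, a: int, b: int) -> list[tuple[float, int]]:
        """Jumps (forward time in (0, T), new state) on one homogeneous piece."""
        Q = self.engine.Q(epoch)
        mu = float(-Q.diagonal().min())
        if mu <= 0:
            if a != b:
                raise RuntimeError("zero-rate segment with differing endpoints")
            return []
        mu *= 1.05
        R = np.eye(Q.shape[0]) + Q / mu
        P_T = self.engine.segment_P(epoch, T)
        p_ab = P_T[a, b]
        if p_ab <= 0:
            raise RuntimeError("endpoint pair has zero probability")
        # sample the number of uniformized jumps N: P(N=n) = pois(mu T, n) R^n[a,b] / p_ab
        u = self.rng.uniform() * p_ab
        pois = np.exp(-mu * T)
        Rpow = [np.eye(Q.shape[0])]
        acc = pois * Rpow[0][a, b]
        n = 0
        while acc < u:
            n += 1
            if n > self.max_jumps:
                raise RuntimeError("uniformization jump count exceeded the cap")
            pois *= mu * T / n
            Rpow.append(Rpow[-1] @ R)
            acc += pois * Rpow[n][a, b]
        if n == 0:
            return []
        times = np.sort(self.rng.uniform(0.0, T, size=n))
        states = [a]
        for i in range(1, n):
            w = R[states[-1], :] * Rpow[n - i][:, b]
            total = w.sum()
            if total <= 0:
                raise RuntimeError("degenerate intermediate-state weights")
            states.append(int(self.rng.choice(w.size, p=w / total)))
        states.append(b)
        # drop virtual (self) jumps
        return [
            (float(times[i]), states[i + 1])
            for i in range(n)
            if states[i + 1] != states[i]
        ]

    def sample_branch(
        self, t_bottom: float, t_top: float, top_state: int, bottom_state: int
    ) -> list[tuple[float, int, int]]:
        """(age, from_state, to_state) changes along a branch, oldest first."""
        segments = list(reversed(_branch_segments(t_bottom, t_top, self.engine.dmm)))
        # segments now run top (old) -> bottom (young); pick states at the cuts
        states = [top_state]
        age_hi = t_top
        boundary_ages = []
        for dt, _ in segments[:-1]:
            boundary_ages.append(age_hi - dt)
            age_hi -= dt
        for k, cut_age in enumerate(boundary_ages):
            dt_k, ep_k = segments[k]
            P_first = self.engine.segment_P(ep_k, dt_k)
            P_rest = None
            for dt, ep in segments[k + 1 :]:
                Pe = self.engine.segment_P(ep, dt)
                P_rest = Pe if P_rest is None else P_rest @ Pe
            w = P_first[states[-1], :] * P_rest[:, bottom_state]
            total = w.sum()
            if total <= 0:
                raise RuntimeError("no feasible state at an epoch boundary")
            states.append(int(self.rng.choice(w.size, p=w / total)))
        states.append(bottom_state)

        changes: list[tuple[float, int, int]] = []
        age_hi = t_top
        for k, (dt, epoch) in enumerate(segments):
            jumps = self.sample_segment(epoch, dt, states[k], states[k + 1])
            cur = states[k]
            for fwd_t, new_state in jumps:
                changes.append((age_hi - fwd_t, cur, new_state))
                cur = new_state
            age_hi -= dt
        return changes


def sample_history(
    clade: CladeDataset,
    dmm: StratifiedDMM,
    model: str,
    params: ModelParams,
    seed: int | None = None,
    max_range_size: int | None = None,
    replicate: int = 0,
    max_retries: int = 1000,
) -> EventLog:
    """Draw one stochastic map conditional on the model and the tip ranges."""
    engine = _Engine(clade, dmm, model, params, max_range_size)
    rng = np.random.default_rng(seed)
    space = engine.space
    tree = clade.tree
    L, _ = engine.downpass()
    if L is None:
        raise ValueError("tip data have zero likelihood under these parameters")
    sampler = _PathSampler(engine, rng)

    for _attempt in range(max_retries):
        try:
            return _sample_once(engine, sampler, rng, L, replicate)
        except RuntimeError:
            continue
    raise RuntimeError(f"stochastic map sampling failed after {max_retries} retries")


def _sample_once(engine: _Engine, sampler: _PathSampler, rng, L, replicate: int) -> EventLog:
    clade, space, tree = engine.clade, engine.space, engine.clade.tree
    log = EventLog(replicate=replicate, n_realms=clade.n_realms, node_states={}, branch_states={})

    root = tree.root
    w = L[root.index].copy()
    w[0] = 0.0
    total = w.sum()
    if total <= 0:
        raise ValueError("root likelihood vanished")
    node_state: dict[int, int] = {root.index: int(rng.choice(w.size, p=w / total))}

    for node in tree.preorder():
        if node.is_leaf:
            continue
        a = node_state[node.index]
        log.node_states[node.index] = space.states[a]
        table = engine.clado(engine.dmm.epoch_index(node.age))
        li, ri, types, probs = table.events[a]
        up = [engine.branch_P(c.age, node.age) @ L[c.index] for c in node.children]
        ew = probs * up[0][li] * up[1][ri]
        etotal = ew.sum()
        if etotal <= 0:
            raise RuntimeError("no feasible cladogenetic event")
        ei = int(rng.choice(ew.size, p=ew / etotal))
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
            P = engine.branch_P(child.age, node.age)
            bw = P[top, :] * L[child.index]
            btotal = bw.sum()
            if btotal <= 0:
                raise RuntimeError("no feasible branch-bottom state")
            bottom = int(rng.choice(bw.size, p=bw / btotal))
            node_state[child.index] = bottom
            log.branch_states[child.index] = (space.states[top], space.states[bottom])
            for age, s_from, s_to in sampler.sample_branch(child.age, node.age, top, bottom):
                log.anagenetic.append(
                    AnageneticEvent(
                        branch_id=child.index,
                        time=age,
                        from_bits=space.states[s_from],
                        to_bits=space.states[s_to],
                    )
                )
    for tip in tree.tips:
        if tip.index in node_state:
            log.node_states[tip.index] = space.states[node_state[tip.index]]
    return log


def run_bsm(
    clade: CladeDataset,
    fit: FitResult,
    dmm: StratifiedDMM,
    n_maps: int = 50,
    seed: int | None = None,
    max_range_size: int | None = None,
) -> list[EventLog]:
    """Draw ``n_maps`` independent stochastic maps (deterministic per seed)."""
    seeds = np.random.SeedSequence(seed).spawn(n_maps)
    return [
        sample_history(
            clade,
            dmm,
            fit.model,
            fit.params,
            seed=seeds[i],
            max_range_size=max_range_size,
            replicate=i + 1,
        )
        for i in range(n_maps)
    ]


def replay_is_consistent(log: EventLog, clade: CladeDataset) -> bool:
    """Replay each branch's anagenetic events and check the endpoint states."""
    by_branch: dict[int, list[AnageneticEvent]] = {}
    for ev in log.anagenetic:
        by_branch.setdefault(ev.branch_id, []).append(ev)
    for branch_id, (top, bottom) in log.branch_states.items():
        state = top
        for ev in sorted(by_branch.get(branch_id, []), key=lambda e: -e.time):
            if ev.from_bits != state:
                return False
            state = ev.to_bits
        if state != bottom:
            return False
    # tip states must match the observed ranges
    for tip in clade.tree.tips:
        if log.node_states.get(tip.index) != clade.ranges[tip.label].bits:
            return False
    return True


def _spread(bits: int) -> tuple[tuple[int, float], ...]:
    members = [i for i in range(bits.bit_length()) if bits >> i & 1]
    w = 1.0 / len(members)
    return tuple((i, w) for i in members)


def classify_events(log: EventLog) -> list[EventRecord]:
    """Convert a sampled history into typed, realm-attributed event records.

    Anagenetic gains become dispersal (destination = gained realm, source
    split 1/|R| over the occupied realms); losses become extinction in the
    lost realm.  Cladogenetic sympatry/copying is in-situ speciation spread
    1/|R| over the sympatric range, subset sympatry is attributed to the
    nested single-realm daughter, vicariance becomes allopatry, and founder
    events record the jump realm as destination with 1/|R| source weights.
    """
    records: list[EventRecord] = []
    for ev in log.anagenetic:
        gained = ev.to_bits & ~ev.from_bits
        lost = ev.from_bits & ~ev.to_bits
        if gained and not lost:
            records.append(
                EventRecord(
                    etype=DISPERSAL,
                    time=ev.time,
                    branch_id=ev.branch_id,
                    source=_spread(ev.from_bits),
                    dest=gained.bit_length() - 1,
                )
            )
        elif lost and not gained:
            records.append(
                EventRecord(
                    etype=EXTINCTION,
                    time=ev.time,
                    branch_id=ev.branch_id,
                    realms=(lost.bit_length() - 1,),
                )
            )
        else:
            raise ValueError(f"unrecognized anagenetic change {ev.from_bits:b}->{ev.to_bits:b}")
    for ev in log.cladogenetic:
        anc = ev.ancestor_bits
        if ev.etype == NARROW_SYMPATRY:
            records.append(
                EventRecord(
                    etype=IN_SITU,
                    time=ev.time,
                    branch_id=ev.node_id,
                    source=_spread(anc),
                    realms=tuple(i for i, _ in _spread(anc)),
                )
            )
        elif ev.etype == SUBSET_SYMPATRY:
            nested = ev.left_bits if ev.left_bits.bit_count() == 1 else ev.right_bits
            records.append(
                EventRecord(
                    etype=SUBSET,
                    time=ev.time,
                    branch_id=ev.node_id,
                    source=((nested.bit_length() - 1, 1.0),),
                    realms=(nested.bit_length() - 1,),
                )
            )
        elif ev.etype == VICARIANCE:
            records.append(
                EventRecord(
                    etype=ALLOPATRY,
                    time=ev.time,
                    branch_id=ev.node_id,
                    source=_spread(anc),
                    realms=tuple(i for i, _ in _spread(anc)),
                )
            )
        elif ev.etype == FOUNDER:
            jump = ev.left_bits if ev.left_bits & ~anc else ev.right_bits
            records.append(
                EventRecord(
                    etype=FOUNDER_SPECIATION,
                    time=ev.time,
                    branch_id=ev.node_id,
                    source=_spread(anc),
                    dest=jump.bit_length() - 1,
                )
            )
        else:
            raise ValueError(f"unknown cladogenetic event code {ev.etype!r}")
    return records
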