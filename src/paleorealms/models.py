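"""Dispersal-extinction-cladogenesis range evolution models.

Six models are supported: DEC, DIVALIKE and BAYAREALIKE, each with or
without founder-event speciation (+J).  The anagenetic part is a CTMC over
realm subsets: range expansion into realm k at rate d * sum of multipliers
from the occupied realms, loss of an occupied realm at rate e, the empty
range absorbing.  The cladogenetic part assigns daughter ranges at nodes:

* DEC        : narrow sympatry, subset sympatry, narrow vicariance
* DIVALIKE   : narrow sympatry, vicariance of any split
* BAYAREALIKE: range copying only (widespread sympatry)
* +J variants add founder events (one daughter jumps outside the range),
  weighted by j times the mean dispersal multiplier from the occupied
  realms to the jump destination.

Likelihoods use Felsenstein pruning with per-branch matrix exponentials,
branches split at the stratified-DMM epoch boundaries, a flat root prior
over non-empty ranges, and per-node rescaling against underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, inf, log
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .core import CladeDataset, ModelParams, Phylogeny, RangeState
from .dmm import StratifiedDMM

__all__ = [
    "MODEL_NAMES",
    "StateSpace",
    "CladoTable",
    "FitResult",
    "enumerate_states",
    "build_Q",
    "build_clado_table",
    "loglikelihood",
    "fit_model",
    "model_select",
]

MODEL_NAMES = ("DEC", "DEC+J", "DIVALIKE", "DIVALIKE+J", "BAYAREALIKE", "BAYAREALIKE+J")

NARROW_SYMPATRY = "narrow_sympatry"
SUBSET_SYMPATRY = "subset_sympatry"
VICARIANCE = "vicariance"
FOUNDER = "founder"


def _parse_model(model: str) -> tuple[str, bool]:
    base, _, suffix = model.partition("+")
    if base not in ("DEC", "DIVALIKE", "BAYAREALIKE") or suffix not in ("", "J"):
        raise ValueError(f"unknown model {model!r}")
    return base, suffix == "J"


class StateSpace:
    """Ordered realm subsets up to a maximum range size (empty range first)."""

    def __init__(self, n_realms: int, max_size: int | None = None):
        if max_size is None:
            max_size = n_realms
        if not 1 <= max_size <= n_realms:
            raise ValueError("max_size must be in [1, n_realms]")
        self.n_realms = n_realms
        self.max_size = max_size
        states = [0]
        for size in range(1, max_size + 1):
            states.extend(
                sorted(sum(1 << i for i in combo) for combo in combinations(range(n_realms), size))
            )
        self.states: list[int] = states
        self.index: dict[int, int] = {s: i for i, s in enumerate(states)}
        self.sizes = np.array([s.bit_count() for s in states])

    def __len__(self) -> int:
        return len(self.states)

    def state_of(self, rs: RangeState) -> int:
        """Index of a RangeState (errors if it exceeds the size cap)."""
        if rs.n_realms != self.n_realms:
            raise ValueError("RangeState realm count does not match the state space")
        try:
            return self.index[rs.bits]
        except KeyError:
            raise ValueError(
                f"range of size {rs.size} exceeds the cap {self.max_size}"
            ) from None


def enumerate_states(n_realms: int, max_size: int | None = None) -> StateSpace:
    return StateSpace(n_realms, max_size)


def build_Q(params: ModelParams, M: np.ndarray, space: StateSpace) -> np.ndarray:
    """Anagenetic rate matrix over the state space for one epoch.

    rate(R -> R+{k}) = d * sum_{i in R} M[i, k]; rate(R -> R-{i}) = e; the
    empty range is absorbing.  Rows sum to zero.
    """
    n = space.n_realms
    if M.shape != (n, n):
        raise ValueError("multiplier matrix does not match the realm count")
    S = len(space)
    Q = np.zeros((S, S))
    for a, bits in enumerate(space.states):
        if bits == 0:
            continue
        occupied = [i for i in range(n) if bits >> i & 1]
        if len(occupied) < space.max_size:
            for k in range(n):
                if bits >> k & 1:
                    continue
                rate = params.d * sum(M[i, k] for i in occupied)
                if rate > 0:
                    Q[a, space.index[bits | (1 << k)]] += rate
        for i in occupied:
            Q[a, space.index[bits ^ (1 << i)]] += params.e
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


@dataclass
class CladoTable:
    """Per-ancestral-state cladogenetic event distributions.

    For ancestral state index ``a``, ``events[a]`` holds parallel arrays of
    left/right daughter state indices, event-type codes and probabilities
    (summing to one).  The empty range has no events.
    """

    space: StateSpace
    events: dict[int, tuple[np.ndarray, np.ndarray, list[str], np.ndarray]]

    def probabilities(self, a: int):
        return self.events[a]


def build_clado_table(
    model: str, params: ModelParams, space: StateSpace, M: np.ndarray
) -> CladoTable:
    """Enumerate allowed daughter pairs per ancestral state and normalize.

    Weights: narrow sympatry y, subset sympatry s, vicariance v (each ordered
    event), founder j * mean multiplier from the occupied realms to the jump
    destination.  Unordered splits are expanded to both daughter orders.
    """
    base, plus_j = _parse_model(model)
    n = space.n_realms
    events: dict[int, tuple] = {}
    for a, bits in enumerate(space.states):
        if bits == 0:
            continue
        occupied = [i for i in range(n) if bits >> i & 1]
        left, right, types, weights = [], [], [], []

        def add(lb: int, rb: int, etype: str, w: float) -> None:
            if w <= 0:
                return
            left.append(space.index[lb])
            right.append(space.index[rb])
            types.append(etype)
            weights.append(w)

        if len(occupied) == 1:
            add(bits, bits, NARROW_SYMPATRY, params.y)
        else:
            if base == "DEC":
                for i in occupied:
                    add(1 << i, bits, SUBSET_SYMPATRY, params.s)
                    add(bits, 1 << i, SUBSET_SYMPATRY, params.s)
                for i in occupied:  # narrow vicariance: one singleton daughter
                    rest = bits ^ (1 << i)
                    add(1 << i, rest, VICARIANCE, params.v)
                    if rest.bit_count() > 1:  # avoid double-counting 1|1 splits
                        add(rest, 1 << i, VICARIANCE, params.v)
            elif base == "DIVALIKE":
                for split in _bipartitions(bits):
                    s1, s2 = split
                    add(s1, s2, VICARIANCE, params.v)
                    add(s2, s1, VICARIANCE, params.v)
            elif base == "BAYAREALIKE":
                add(bits, bits, NARROW_SYMPATRY, params.y)
        if plus_j and params.j > 0:
            for k in range(n):
                if bits >> k & 1:
                    continue
                m = float(np.mean([M[i, k] for i in occupied]))
                w = params.j * m
                add(bits, 1 << k, FOUNDER, w)
                add(1 << k, bits, FOUNDER, w)

        total = float(sum(weights))
        if total <= 0:
            raise ValueError(
                f"no cladogenetic event has positive weight for state {bits:b}"
            )
        events[a] = (
            np.array(left, dtype=int),
            np.array(right, dtype=int),
            types,
            np.array(weights) / total,
        )
    return CladoTable(space, events)


def _bipartitions(bits: int):
    """Unordered splits of a range into two disjoint non-empty parts."""
    members = [i for i in range(bits.bit_length()) if bits >> i & 1]
    seen = set()
    for r in range(1, len(members)):
        for combo in combinations(members, r):
            s1 = sum(1 << i for i in combo)
            s2 = bits ^ s1
            key = (min(s1, s2), max(s1, s2))
            if key not in seen:
                seen.add(key)
                yield s1, s2


# -- pruning likelihood ------------------------------------------------------

def _branch_segments(t_bottom: float, t_top: float, dmm: StratifiedDMM):
    """(duration, epoch index) pieces of a branch, ordered bottom (young) up."""
    cuts = dmm.boundaries[(dmm.boundaries > t_bottom + 1e-12) & (dmm.boundaries < t_top - 1e-12)]
    ages = [t_bottom, *cuts, t_top]
    return [
        (ages[i + 1] - ages[i], dmm.epoch_index(0.5 * (ages[i] + ages[i + 1])))
        for i in range(len(ages) - 1)
    ]


class _Engine:
    """Caches Q matrices, clado tables and branch propagators for one model."""

    def __init__(
        self,
        clade: CladeDataset,
        dmm: StratifiedDMM,
        model: str,
        params: ModelParams,
        max_range_size: int | None = None,
    ):
        self.clade = clade
        self.dmm = dmm
        self.model = model
        self.params = params
        n = clade.n_realms
        if dmm.realms.count != n:
            raise ValueError("DMM realm count does not match the clade's ranges")
        dmm.validate_root_age(clade.tree.root_age)
        self.space = StateSpace(n, max_range_size)
        self._Q: dict[int, np.ndarray] = {}
        self._clado: dict[int, CladoTable] = {}
        self._P: dict[tuple[int, float], np.ndarray] = {}

    def Q(self, epoch: int) -> np.ndarray:
        if epoch not in self._Q:
            self._Q[epoch] = build_Q(self.params, self.dmm.matrices[epoch], self.space)
        return self._Q[epoch]

    def clado(self, epoch: int) -> CladoTable:
        if epoch not in self._clado:
            self._clado[epoch] = build_clado_table(
                self.model, self.params, self.space, self.dmm.matrices[epoch]
            )
        return self._clado[epoch]

    def segment_P(self, epoch: int, dt: float) -> np.ndarray:
        key = (epoch, round(dt, 12))
        if key not in self._P:
            self._P[key] = expm(self.Q(epoch) * dt)
        return self._P[key]

    def branch_P(self, t_bottom: float, t_top: float) -> np.ndarray:
        """Transition matrix from the branch top (older) to its bottom."""
        P = None
        for dt, epoch in reversed(_branch_segments(t_bottom, t_top, self.dmm)):
            Pe = self.segment_P(epoch, dt)
            P = Pe if P is None else P @ Pe
        if P is None:
            P = np.eye(len(self.space))
        return P

    def downpass(self, tip_vectors: dict | None = None):
        """Scaled conditional likelihoods at every node (pre-branch, post-clado).

        Returns (L, logscale) where L[node.index] is the conditional
        likelihood of the data below the node given the node's state, and
        ``logscale`` the summed log of the per-node rescaling factors.
        ``tip_vectors`` can replace the one-hot observed tip states with
        arbitrary per-tip constraint vectors (e.g. "any non-empty range").
        """
        space = self.space
        tree = self.clade.tree
        L = np.zeros((len(tree.postorder()), len(space)))
        logscale = 0.0
        for node in tree.postorder():
            if node.is_leaf:
                if tip_vectors is not None:
                    L[node.index] = tip_vectors[node.label]
                else:
                    L[node.index, space.state_of(self.clade.ranges[node.label])] = 1.0
                continue
            if len(node.children) != 2:
                raise ValueError("trees must be strictly bifurcating")
            up = []
            for child in node.children:
                P = self.branch_P(child.age, node.age)
                up.append(P @ L[child.index])
            table = self.clado(self.dmm.epoch_index(node.age))
            row = np.zeros(len(space))
            for a in table.events:
                li, ri, _, probs = table.events[a]
                row[a] = float(np.sum(probs * up[0][li] * up[1][ri]))
            mx = row.max()
            if mx <= 0:
                return None, -inf
            L[node.index] = row / mx
            logscale += log(mx)
        return L, logscale

    def survival_logprob(self) -> float:
        """Log-probability that every tip range is non-empty under the model."""
        v = np.ones(len(self.space))
        v[0] = 0.0
        tip_vectors = {label: v for label in self.clade.tree.tip_labels}
        L, logscale = self.downpass(tip_vectors=tip_vectors)
        if L is None:
            return -inf
        root = L[self.clade.tree.root.index].copy()
        root[0] = 0.0
        val = root[1:].mean()
        return (log(val) + logscale) if val > 0 else -inf

    def loglikelihood(self, condition_survival: bool = False) -> float:
        lnl = self._loglikelihood()
        if condition_survival and np.isfinite(lnl):
            lnl -= self.survival_logprob()
        return lnl

    def _loglikelihood(self) -> float:
        if self.clade.tree.n_tips == 1:
            # degenerate single-tip clade: probability of the observed tip range
            # under a flat prior over non-empty root states and pure anagenesis
            tip = self.clade.tree.tips[0]
            v = np.zeros(len(self.space))
            v[self.space.state_of(self.clade.ranges[tip.label])] = 1.0
            P = self.branch_P(0.0, self.clade.tree.root_age)
            root = P @ v
            root[0] = 0.0
            val = root[1:].mean()
            return log(val) if val > 0 else -inf
        L, logscale = self.downpass()
        if L is None:
            return -inf
        root = L[self.clade.tree.root.index].copy()
        root[0] = 0.0  # flat prior over non-empty states
        val = root[1:].mean()
        return (log(val) + logscale) if val > 0 else -inf


def loglikelihood(
    clade: CladeDataset,
    dmm: StratifiedDMM,
    model: str,
    params: ModelParams,
    max_range_size: int | None = None,
    condition_survival: bool = False,
) -> float:
    """Log-likelihood of the tip ranges under one model (pruning algorithm).

    With ``condition_survival`` the likelihood is divided by the probability
    that every tip range is non-empty — the correct likelihood for data
    generated by resampling until no tip range went extinct.
    """
    return _Engine(clade, dmm, model, params, max_range_size).loglikelihood(
        condition_survival
    )


# -- maximum-likelihood fitting ---------------------------------------------

@dataclass
class FitResult:
    """One model's maximum-likelihood fit on one clade."""

    model: str
    params: ModelParams
    lnL: float
    k: int
    converged: bool = True
    data_id: str = ""

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.lnL


DEFAULT_BOUNDS = {"d": (1e-9, 5.0), "e": (1e-9, 5.0), "j": (0.0, 2.99999)}


def fit_model(
    clade: CladeDataset,
    dmm: StratifiedDMM,
    model: str,
    max_range_size: int | None = None,
    n_starts: int = 5,
    seed: int | None = None,
    bounds: dict | None = None,
    condition_survival: bool = False,
) -> FitResult:
    """Maximize the log-likelihood over (d, e[, j]) with multi-start L-BFGS-B.

    d and e are optimized on a log10 scale; the first start is a fixed
    moderate point and the remaining ones are drawn log-uniformly (seeded).
    """
    base, plus_j = _parse_model(model)
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    rng = np.random.default_rng(seed)
    lo_d, hi_d = np.log10(b["d"][0]), np.log10(b["d"][1])
    lo_e, hi_e = np.log10(b["e"][0]), np.log10(b["e"][1])

    def unpack(x) -> ModelParams:
        d, e = 10.0 ** x[0], 10.0 ** x[1]
        j = float(x[2]) if plus_j else 0.0
        return ModelParams(d=d, e=e, j=j)

    def neg_lnl(x) -> float:
        val = loglikelihood(
            clade, dmm, model, unpack(x), max_range_size, condition_survival
        )
        return 1e10 if not np.isfinite(val) else -val

    starts = [np.array([-1.0, -1.5, 0.1] if plus_j else [-1.0, -1.5])]
    for _ in range(max(n_starts - 1, 0)):
        x = [rng.uniform(max(lo_d, -4), hi_d), rng.uniform(max(lo_e, -4), hi_e)]
        if plus_j:
            x.append(rng.uniform(b["j"][0], min(b["j"][1], 1.5)))
        starts.append(np.array(x))

    opt_bounds = [(lo_d, hi_d), (lo_e, hi_e)] + ([(b["j"][0], b["j"][1])] if plus_j else [])
    best, best_val, converged = None, np.inf, False
    for x0 in starts:
        res = minimize(neg_lnl, x0[: len(opt_bounds)], method="L-BFGS-B", bounds=opt_bounds)
        if res.fun < best_val:
            best, best_val, converged = res.x, res.fun, bool(res.success)
    return FitResult(
        model=model,
        params=unpack(best),
        lnL=-best_val,
        k=3 if plus_j else 2,
        converged=converged,
        data_id=_data_id(clade),
    )


def _data_id(clade: CladeDataset) -> str:
    items = sorted((name, rs.bits) for name, rs in clade.ranges.items())
    return f"{clade.group}:{hash(tuple(items)) & 0xFFFFFFFF:08x}"


def model_select(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fits by AIC (ascending), ties broken by fewer parameters.

    All fits must come from the same clade.  The returned frame has one row
    per model with a ``delta_aic`` column; the first row is the best model.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to select among")
    ids = {f.data_id for f in fits}
    if len(ids) > 1:
        raise ValueError("fits come from different clades")
    rows = [
        {
            "model": f.model,
            "d": f.params.d,
            "e": f.params.e,
            "j": f.params.j,
            "lnL": f.lnL,
            "k": f.k,
            "AIC": f.aic,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values(["AIC", "k"], kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["AIC"] - df["AIC"].iloc[0]
    return df
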