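"""Independent oracles used by the test suite.

These deliberately avoid the package's pruning/likelihood code paths:
transition matrices come straight from scipy's expm, and subtree
likelihoods are explicit sums over states and cladogenetic events.
"""

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm

from paleorealms.models import StateSpace, _branch_segments, build_Q, build_clado_table


def exhaustive_loglikelihood(clade, dmm, model, params):
    """Explicit state-sum likelihood (memoized over (node, state))."""
    tree = clade.tree
    space = StateSpace(clade.n_realms)
    S = len(space)
    tipstate = {t.index: space.index[clade.ranges[t.label].bits] for t in tree.tips}

    def branch_P(child, parent):
        P = np.eye(S)
        for dt, ep in reversed(_branch_segments(child.age, parent.age, dmm)):
            P = P @ expm(build_Q(params, dmm.matrices[ep], space) * dt)
        return P

    Pmat, clado = {}, {}
    for n in tree.postorder():
        if n.is_leaf:
            continue
        clado[n.index] = build_clado_table(
            model, params, space, dmm.matrices[dmm.epoch_index(n.age)]
        )
        for c in n.children:
            Pmat[c.index] = branch_P(c, n)

    memo = {}

    def node_lik(node, a):
        key = (node.index, a)
        if key in memo:
            return memo[key]
        if node.is_leaf:
            val = 1.0 if tipstate[node.index] == a else 0.0
        elif a == 0 or a not in clado[node.index].events:
            val = 0.0
        else:
            li, ri, _, pr = clado[node.index].events[a]
            val = 0.0
            for k in range(len(pr)):
                left = sum(
                    Pmat[node.children[0].index][li[k], b] * node_lik(node.children[0], b)
                    for b in range(S)
                )
                right = sum(
                    Pmat[node.children[1].index][ri[k], b] * node_lik(node.children[1], b)
                    for b in range(S)
                )
                val += pr[k] * left * right
        memo[key] = val
        return val

    mean = np.mean([node_lik(tree.root, a) for a in range(1, S)])
    return np.log(mean) if mean > 0 else -np.inf


def conditional_expected_transitions(Q, T, a, b):
    """E[number of transitions | X(0)=a, X(T)=b] for a CTMC, by quadrature."""
    P_T = expm(Q * T)
    n = Q.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j or Q[i, j] == 0:
                continue
            val, _ = quad(
                lambda t: expm(Q * t)[a, i] * expm(Q * (T - t))[j, b],
                0.0,
                T,
                epsabs=1e-12,
                limit=200,
            )
            total += Q[i, j] * val
    return total / P_T[a, b]


def wilcoxon_exact_enumeration(d, alternative="two-sided"):
    """Exact signed-rank p-value by enumerating all 2^n sign patterns."""
    from itertools import product

    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    V_obs = ranks[d > 0].sum()
    vs = [sum(r for r, s in zip(ranks, signs) if s) for signs in product([0, 1], repeat=n)]
    vs = np.array(vs)
    total = vs.size
    if alternative == "greater":
        return np.sum(vs >= V_obs) / total
    if alternative == "less":
        return np.sum(vs <= V_obs) / total
    mean = n * (n + 1) / 4.0
    dev = abs(V_obs - mean)
    return np.sum(np.abs(vs - mean) >= dev - 1e-12) / total
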