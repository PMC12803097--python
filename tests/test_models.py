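import numpy as np
import pytest
from scipy.linalg import expm

from paleorealms.core import CladeDataset, ModelParams, RangeState, RealmSet, parse_newick
from paleorealms.dmm import StratifiedDMM
from paleorealms.models import (
    MODEL_NAMES,
    FitResult,
    StateSpace,
    build_clado_table,
    build_Q,
    enumerate_states,
    fit_model,
    loglikelihood,
    model_select,
)

from _oracles import exhaustive_loglikelihood


class TestStateSpace:
    @pytest.mark.parametrize(
        "n,cap,expected",
        [(2, 2, 4), (9, 9, 512), (9, 4, 1 + 9 + 36 + 84 + 126)],
    )
    def test_state_counts(self, n, cap, expected):
        assert len(enumerate_states(n, cap)) == expected

    def test_canonical_order(self):
        space = enumerate_states(3)
        assert space.states[0] == 0  # empty first
        sizes = [s.bit_count() for s in space.states]
        assert sizes == sorted(sizes)

    def test_cap_violation_raises(self):
        space = enumerate_states(3, max_size=1)
        with pytest.raises(ValueError, match="cap"):
            space.state_of(RangeState(0b011, 3))


class TestRateMatrix:
    def test_direct_rates(self):
        space = enumerate_states(2)
        Q = build_Q(ModelParams(d=0.1, e=0.05), np.ones((2, 2)), space)
        iA, iB, iAB = space.index[1], space.index[2], space.index[3]
        assert Q[iA, iAB] == pytest.approx(0.1)
        assert Q[iAB, iA] == pytest.approx(0.05)
        assert Q[iA, 0] == pytest.approx(0.05)
        assert Q[0].sum() == 0.0  # empty range absorbing

    def test_multiplier_scaling(self):
        space = enumerate_states(2)
        M = np.array([[1.0, 0.5], [0.5, 1.0]])
        Q = build_Q(ModelParams(d=0.1, e=0.05), M, space)
        assert Q[space.index[1], space.index[3]] == pytest.approx(0.05)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        space = enumerate_states(4)
        x = rng.uniform(0, 1, (4, 4))
        M = (x + x.T) / 2
        np.fill_diagonal(M, 1.0)
        Q = build_Q(ModelParams(d=0.3, e=0.1), M, space)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_transition_matrix_is_stochastic(self):
        space = enumerate_states(3)
        Q = build_Q(ModelParams(d=0.2, e=0.1), np.ones((3, 3)), space)
        for t in (0.1, 1.0, 10.0):
            P = expm(Q * t)
            assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
            assert P.min() > -1e-12


class TestCladoTables:
    def test_dec_single_realm_ancestor(self):
        space = enumerate_states(2)
        table = build_clado_table("DEC", ModelParams(d=0.1, e=0.1), space, np.ones((2, 2)))
        li, ri, types, probs = table.events[space.index[1]]
        assert len(probs) == 1 and probs[0] == 1.0
        assert space.states[li[0]] == 1 and space.states[ri[0]] == 1

    def test_dec_two_realm_ancestor_six_events(self):
        space = enumerate_states(2)
        table = build_clado_table("DEC", ModelParams(d=0.1, e=0.1), space, np.ones((2, 2)))
        li, ri, types, probs = table.events[space.index[3]]
        assert len(probs) == 6
        assert np.allclose(probs, 1 / 6)
        assert types.count("subset_sympatry") == 4
        assert types.count("vicariance") == 2

    def test_bayarealike_copying_only(self):
        space = enumerate_states(2)
        table = build_clado_table("BAYAREALIKE", ModelParams(d=0.1, e=0.1), space, np.ones((2, 2)))
        li, ri, types, probs = table.events[space.index[3]]
        assert len(probs) == 1
        assert space.states[li[0]] == 3 and space.states[ri[0]] == 3

    def test_probabilities_normalize(self):
        space = enumerate_states(3)
        M = np.array([[1, 0.4, 0.9], [0.4, 1, 0.2], [0.9, 0.2, 1.0]])
        for model in MODEL_NAMES:
            table = build_clado_table(model, ModelParams(d=0.1, e=0.1, j=0.5), space, M)
            for a, (_, _, _, probs) in table.events.items():
                assert probs.sum() == pytest.approx(1.0)


class TestLikelihood:
    def test_cherry_zero_rates_equals_one_third(self, cherry_clade, uniform_dmm2):
        lnl = loglikelihood(cherry_clade, uniform_dmm2, "DEC", ModelParams())
        assert lnl == pytest.approx(np.log(1 / 3), abs=1e-12)

    def test_plus_j_nests_base_models(self, small_clade, uniform_dmm3):
        clade, _, cfg = small_clade
        for base in ("DEC", "DIVALIKE", "BAYAREALIKE"):
            l0 = loglikelihood(clade, uniform_dmm3, base, cfg.params)
            l1 = loglikelihood(clade, uniform_dmm3, base + "+J", cfg.params)
            assert l1 == pytest.approx(l0, abs=1e-9)

    def test_matches_exhaustive_oracle_small_fixture(self, stratified_dmm3):
        rng = np.random.default_rng(12)
        tree = parse_newick("(((a:1,b:1):1,c:2):1,d:3);")
        for model in ("DEC+J", "DIVALIKE"):
            ranges = {t: RangeState(int(rng.integers(1, 8)), 3) for t in tree.tip_labels}
            clade = CladeDataset(tree, ranges)
            p = ModelParams(d=0.2, e=0.1, j=0.7 if "+J" in model else 0.0)
            assert loglikelihood(clade, stratified_dmm3, model, p) == pytest.approx(
                exhaustive_loglikelihood(clade, stratified_dmm3, model, p), abs=1e-10
            )

    def test_permutation_equivariance(self, uniform_dmm3):
        # relabeling realms leaves the likelihood unchanged on symmetric DMMs
        tree = parse_newick("((a:1,b:1):1,(c:1.5,d:1.5):0.5);")
        perm = [2, 0, 1]
        ranges = {"a": 0b001, "b": 0b011, "c": 0b100, "d": 0b110}

        def permute(bits):
            out = 0
            for i in range(3):
                if bits >> i & 1:
                    out |= 1 << perm[i]
            return out

        p = ModelParams(d=0.15, e=0.05)
        c1 = CladeDataset(tree, {k: RangeState(v, 3) for k, v in ranges.items()})
        c2 = CladeDataset(tree, {k: RangeState(permute(v), 3) for k, v in ranges.items()})
        l1 = loglikelihood(c1, uniform_dmm3, "DEC", p)
        l2 = loglikelihood(c2, uniform_dmm3, "DEC", p)
        assert l1 == pytest.approx(l2, abs=1e-10)

    def test_shared_realm_limit(self, uniform_dmm3):
        # e=0 and d -> 0: identical single-realm tips give likelihood 1/(2^n - 1)
        tree = parse_newick("((a:1,b:1):1,c:2);")
        clade = CladeDataset(tree, {t: RangeState(2, 3) for t in ("a", "b", "c")})
        lnl = loglikelihood(clade, uniform_dmm3, "DEC", ModelParams(d=1e-9, e=0.0))
        assert lnl == pytest.approx(np.log(1 / 7), abs=1e-6)

    def test_impossible_data_gives_minus_inf(self, uniform_dmm2):
        tree = parse_newick("(a:1,b:1);")
        clade = CladeDataset(tree, {"a": RangeState(1, 2), "b": RangeState(2, 2)})
        # copying-only cladogenesis with zero anagenetic rates cannot split tips
        assert loglikelihood(clade, uniform_dmm2, "BAYAREALIKE", ModelParams()) == -np.inf

    def test_survival_conditioning_increases_likelihood(self, small_clade, uniform_dmm3):
        clade, _, cfg = small_clade
        plain = loglikelihood(clade, uniform_dmm3, "DEC", cfg.params)
        conditioned = loglikelihood(
            clade, uniform_dmm3, "DEC", cfg.params, condition_survival=True
        )
        assert conditioned > plain  # dividing by P(survival) <= 1


class TestFitting:
    def test_aic_formula(self):
        fit = FitResult(model="DEC", params=ModelParams(), lnL=-100.0, k=2)
        assert fit.aic == pytest.approx(204.0)

    def test_fit_is_seed_stable(self, small_clade, uniform_dmm3):
        clade, _, _ = small_clade
        f1 = fit_model(clade, uniform_dmm3, "DEC", n_starts=3, seed=1)
        f2 = fit_model(clade, uniform_dmm3, "DEC", n_starts=3, seed=2)
        assert f1.lnL == pytest.approx(f2.lnL, abs=1e-3)

    def test_model_select_ranking_and_tie(self):
        a = FitResult("DEC", ModelParams(), lnL=-100.0, k=2, data_id="x")
        b = FitResult("DEC+J", ModelParams(), lnL=-98.0, k=3, data_id="x")
        df = model_select([a, b])
        assert df.iloc[0]["model"] == "DEC+J"
        assert df.iloc[0]["AIC"] == pytest.approx(202.0)
        assert df["delta_aic"].iloc[0] == 0.0
        # equal AIC: base model (fewer parameters) wins
        c = FitResult("DEC+J", ModelParams(), lnL=-99.0, k=3, data_id="x")
        df = model_select([a, c])
        assert df.iloc[0]["model"] == "DEC"

    def test_model_select_rejects_mixed_clades(self):
        a = FitResult("DEC", ModelParams(), lnL=-1.0, k=2, data_id="x")
        b = FitResult("DEC+J", ModelParams(), lnL=-1.0, k=3, data_id="y")
        with pytest.raises(ValueError, match="different clades"):
            model_select([a, b])

    def test_six_model_table(self, small_clade, uniform_dmm3):
        clade, _, _ = small_clade
        fits = [
            fit_model(clade, uniform_dmm3, m, n_starts=1, seed=0) for m in MODEL_NAMES
        ]
        df = model_select(fits)
        assert len(df) == 6
        assert df["delta_aic"].iloc[0] == 0.0
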