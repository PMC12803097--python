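import numpy as np
import pandas as pd
import pytest

from paleorealms.core import CladeDataset, ModelParams, RangeState, RealmSet, parse_newick
from paleorealms.accounting import (
    binned_series,
    ltt_per_realm,
    process_shares,
    realm_share,
    standardize_by_richness,
    tally,
    top_quantile_edges,
)
from paleorealms.bsm import (
    AnageneticEvent,
    CladogeneticEvent,
    EventLog,
    EventRecord,
    classify_events,
    sample_history,
)
from paleorealms.tables import load_event_rates, load_interchange, load_process_totals


def simple_log(n_realms=2, replicate=1):
    return EventLog(replicate, n_realms, {}, {})


class TestTally:
    def test_single_map_counts(self):
        realms = RealmSet(("A", "B"))
        log = simple_log()
        log.anagenetic.append(AnageneticEvent(0, 3.0, 0b01, 0b11))  # dispersal A->B
        log.anagenetic.append(AnageneticEvent(1, 2.0, 0b11, 0b10))  # extinction in A
        res = tally([[log]], realms)
        assert res.interchange.matrix.loc["A", "B"] == pytest.approx(1.0)
        assert res.interchange.extinction["A"] == pytest.approx(1.0)
        assert res.process_totals["dispersal"] == 1.0
        assert res.process_totals["extinction"] == 1.0

    def test_quantiles_linear_interpolation(self):
        realms = RealmSet(("A", "B"))
        empty = simple_log(replicate=1)
        two = simple_log(replicate=2)
        for _ in range(2):
            two.anagenetic.append(AnageneticEvent(0, 3.0, 0b01, 0b11))
        res = tally([[empty, two]], realms)
        cell = res.table
        assert cell.mean.loc["B", "immigration"] == pytest.approx(1.0)
        assert cell.q025.loc["B", "immigration"] == pytest.approx(0.05)
        assert cell.q975.loc["B", "immigration"] == pytest.approx(1.95)

    def test_tally_matches_naive_recount(self, small_clade):
        # independent oracle: scan the raw log directly
        realms = RealmSet(("A", "B", "C"))
        _, truth, _ = small_clade
        res = tally([[truth]], realms)
        n_gain = sum(
            1 for ev in truth.anagenetic if ev.to_bits.bit_count() > ev.from_bits.bit_count()
        )
        n_loss = len(truth.anagenetic) - n_gain
        founder = sum(1 for ev in truth.cladogenetic if ev.etype == "founder")
        assert res.process_totals["dispersal"] == n_gain
        assert res.process_totals["extinction"] == n_loss
        assert res.process_totals["founder_event_speciation"] == founder
        # conservation: interchange off-diagonal total = dispersal + founder
        assert res.interchange.grand_total == pytest.approx(n_gain + founder)

    def test_unequal_map_counts_rejected(self):
        realms = RealmSet(("A", "B"))
        with pytest.raises(ValueError, match="same number of maps"):
            tally([[simple_log()], [simple_log(), simple_log()]], realms)


class TestProcessShares:
    def test_reproduces_published_percentages(self):
        shares = process_shares(load_process_totals())
        assert shares["in_situ_speciation"] == pytest.approx(39.18479, abs=1e-4)
        assert shares["dispersal"] == pytest.approx(15.93153, abs=1e-4)
        assert shares["extinction"] == pytest.approx(26.19772, abs=1e-4)
        assert load_process_totals().sum() == pytest.approx(44508.6, abs=0.05)
        assert shares.sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_type(self):
        shares = process_shares({"dispersal": 5.0, "extinction": 0.0})
        assert shares["dispersal"] == 100.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            process_shares({"dispersal": 0.0})


class TestStandardization:
    def test_per_species_rate_and_scale(self):
        table = pd.DataFrame({"dispersal": [10.0]}, index=["A"])
        out, excl = standardize_by_richness(table, {"A": 5}, scale=1.0)
        assert out.loc["A", "dispersal"] == pytest.approx(2.0)
        out, _ = standardize_by_richness(table, {"A": 5}, scale=1000.0)
        assert out.loc["A", "dispersal"] == pytest.approx(2000.0)

    def test_low_richness_excluded(self):
        table = pd.DataFrame({"dispersal": [10.0, 3.0]}, index=["A", "B"])
        out, excl = standardize_by_richness(table, {"A": 1, "B": 0})
        assert excl == ["A", "B"]
        assert out.isna().all().all()


class TestRealmShare:
    def test_fish_extinction_share(self):
        t1 = load_event_rates()
        fish = t1[t1.group == "Fishes"].set_index("realm")["extinction"]
        assert realm_share(fish)["CI"] == pytest.approx(7.4, abs=0.05)

    def test_coral_extinction_share_with_exclusions(self):
        t1 = load_event_rates()
        coral = t1[t1.group == "Corals"].set_index("realm")["extinction"]
        share = realm_share(coral, exclude=["NC", "SC", "NP"])
        assert share["CI"] == pytest.approx(14.4, abs=0.05)

    def test_single_included_realm(self):
        assert realm_share({"A": 3.0})["A"] == 100.0
        with pytest.raises(ValueError):
            realm_share({}, exclude=[])


class TestBinnedSeries:
    def test_constant_rate_is_flat(self):
        realms = RealmSet(("A", "B"))
        records = [
            EventRecord("extinction", time=b + 0.5, branch_id=0, realms=(0,))
            for b in range(65)
            for _ in range(5)
        ]
        out = binned_series([records], realms)
        assert np.allclose(out[("A", "extinction")], 5.0)

    def test_impulse_spreads_over_three_windows(self):
        realms = RealmSet(("A", "B"))
        records = [
            EventRecord("extinction", time=10.5, branch_id=0, realms=(0,))
            for _ in range(3)
        ]
        series = binned_series([records], realms)[("A", "extinction")]
        assert series[9] == series[10] == series[11] == pytest.approx(1.0)
        assert series[8] == series[12] == 0.0

    def test_empty_log_zero_series(self):
        realms = RealmSet(("A", "B"))
        out = binned_series([[]], realms)
        assert out[("A", "immigration")].shape == (65,)
        assert np.all(out[("A", "immigration")] == 0)

    def test_events_beyond_span_dropped(self, caplog):
        realms = RealmSet(("A", "B"))
        records = [EventRecord("extinction", time=80.0, branch_id=0, realms=(0,))]
        out = binned_series([records], realms, span=65.0)
        assert np.all(out[("A", "extinction")] == 0)


class TestLtt:
    def test_cherry_hand_construction(self):
        realms = RealmSet(("A", "B"))
        tree = parse_newick("(a:1,b:1);")
        clade = CladeDataset(tree, {"a": RangeState(1, 2), "b": RangeState(1, 2)})
        root = tree.root.index
        tips = {t.label: t.index for t in tree.tips}
        log = EventLog(1, 2, {root: 1, tips["a"]: 1, tips["b"]: 1},
                       {tips["a"]: (1, 1), tips["b"]: (1, 1)})
        out = ltt_per_realm([log], clade, realms)
        assert np.allclose(out["A"]["mean"], 2.0)  # both lineages in A below the root
        assert np.all(out["B"]["mean"] == 0.0)  # never-occupied realm

    def test_zero_rate_ltt_equals_plain_ltt(self, uniform_dmm2):
        realms = RealmSet(("A", "B"))
        tree = parse_newick("((a:1,b:1):1.5,(c:2,d:2):0.5);")
        clade = CladeDataset(tree, {t: RangeState(1, 2) for t in "abcd"})
        log = sample_history(clade, uniform_dmm2, "DEC", ModelParams(), seed=0)
        out = ltt_per_realm([log], clade, realms, bin_width=0.1)
        mids = out["A"]["age"].to_numpy()
        # independent plain LTT: count branch intervals containing each midpoint
        plain = np.zeros_like(mids)
        for node in tree.preorder():
            for child in node.children:
                plain += (mids >= child.age) & (mids < node.age)
        plain[mids >= tree.root_age] = 1
        assert np.allclose(out["A"]["mean"].to_numpy(), plain)


class TestTopQuantileEdges:
    def test_equal_weights_all_kept(self):
        m = pd.DataFrame(np.zeros((3, 3)), index=list("ABC"), columns=list("ABC"))
        m.loc["A", "B"] = m.loc["B", "C"] = m.loc["C", "A"] = m.loc["B", "A"] = 2.0
        edges = top_quantile_edges(m, q=0.25)
        assert len(edges) == 4  # ties at the threshold are kept

    def test_linear_quantile_threshold(self):
        m = pd.DataFrame(np.zeros((4, 4)), index=list("ABCD"), columns=list("ABCD"))
        weights = iter(range(1, 9))
        for i in "ABCD":
            for j in "ABCD":
                if i != j:
                    try:
                        m.loc[i, j] = next(weights)
                    except StopIteration:
                        break
        # positive weights 1..8: the 75th percentile is 6.25, keeping {7, 8}
        edges = top_quantile_edges(m, q=0.25)
        assert sorted(w for _, _, w in edges) == [7.0, 8.0]

    def test_q_one_returns_all_positive(self):
        m = pd.DataFrame([[0, 1.0], [0, 0]], index=list("AB"), columns=list("AB"))
        assert len(top_quantile_edges(m, q=1.0)) == 1
        empty = pd.DataFrame(np.zeros((2, 2)), index=list("AB"), columns=list("AB"))
        assert top_quantile_edges(empty, q=0.25) == []


class TestPublishedInterchange:
    def test_coral_source_and_sink_percentages(self):
        ic = load_interchange("corals")
        src = ic.source_percentages()
        assert src["CI"] == pytest.approx(35.88, abs=0.05)
        assert src["CP"] == pytest.approx(24.46, abs=0.05)
        snk = ic.sink_percentages()
        assert snk["WI"] == pytest.approx(34.56, abs=0.05)
        assert src.sum() == pytest.approx(100.0, abs=1e-9)

    def test_grand_totals_by_group(self):
        for group, total in [("corals", 197.42), ("cetaceans", 125.35),
                             ("seagrass", 77.06), ("fish", 29609.66)]:
            assert load_interchange(group).grand_total == pytest.approx(total, rel=2e-3)
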