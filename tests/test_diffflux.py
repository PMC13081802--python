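"""Differential statistics: BH, Fisher, pooled t, turnover, enrichment."""

import numpy as np
import pandas as pd
import pytest

from lipoflux.diffflux import (
    bh_adjust,
    differential_metabolites,
    differential_reactions,
    fisher_exact_2x2,
    metabolite_turnover,
    subsystem_enrichment,
)
from lipoflux.network import MetabolicNetwork, MetaboliteRecord, ReactionRecord
from oracles import bh_stepup_bruteforce, hypergeom_tail_bruteforce


def flux_matrix(rows: dict, ctrl=("c", 3), treat=("t", 3)):
    cols = [(ctrl[0], f"R{i}") for i in range(1, ctrl[1] + 1)]
    cols += [(treat[0], f"R{i}") for i in range(1, treat[1] + 1)]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=pd.MultiIndex.from_tuples(
        cols, names=["condition", "replicate"]))
    df.index.name = "reaction_id"
    return df


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.05], [0.05]),
            ([0.01, 0.5], [0.02, 0.5]),
        ],
    )
    def test_hand_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_bruteforce_and_statsmodels(self):
        rng = np.random.default_rng(0)
        from statsmodels.stats.multitest import multipletests

        for _ in range(200):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 200)))
            ours = bh_adjust(p)
            assert np.max(np.abs(ours - bh_stepup_bruteforce(p))) < 1e-12
            theirs = multipletests(p, method="fdr_bh")[1]
            assert np.max(np.abs(ours - theirs)) < 1e-12


class TestFisherExact:
    def test_hand_example_17_over_70(self):
        assert fisher_exact_2x2(3, 1, 1, 3, "greater") == pytest.approx(17 / 70, abs=1e-12)

    def test_zero_in_top_left_is_one(self):
        assert fisher_exact_2x2(0, 5, 3, 2, "greater") == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_margin(self):
        assert fisher_exact_2x2(0, 0, 0, 1, "greater") == pytest.approx(1.0, abs=1e-12)

    def test_negative_count_raises(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 1, 1, 1)

    def test_two_sided_matches_scipy(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if a + b + c + d == 0:
                continue
            ours = fisher_exact_2x2(a, b, c, d, "two-sided")
            theirs = scipy_fisher([[a, b], [c, d]], alternative="two-sided").pvalue
            assert ours == pytest.approx(theirs, abs=1e-9)


class TestDifferentialReactions:
    def test_closed_form_example(self):
        m = flux_matrix({"r": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        row = differential_reactions(m, "c", "t", epsilon=0.0).iloc[0]
        assert row["t"] == pytest.approx(3.6742, abs=1e-4)
        assert row["p"] == pytest.approx(0.0214, abs=1e-3)
        assert row["log2FC"] == pytest.approx(1.3219, abs=1e-4)
        assert row["p_adj"] >= row["p"]

    def test_identical_groups(self):
        m = flux_matrix({"r": [2.0, 2.0, 2.0, 2.0, 2.0, 2.0]})
        row = differential_reactions(m, "c", "t").iloc[0]
        assert row["log2FC"] == 0.0 and row["p"] == 1.0
        assert row["degenerate_variance"]

    def test_degenerate_variance_unequal_means(self):
        m = flux_matrix({"r": [1.0, 1.0, 1.0, 2.0, 2.0, 2.0]})
        row = differential_reactions(m, "c", "t").iloc[0]
        assert row["p"] == 0.0 and row["degenerate_variance"]

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        m = flux_matrix({f"r{i}": rng.normal(size=6).tolist() for i in range(20)})
        fwd = differential_reactions(m, "c", "t", epsilon=1e-6)
        rev = differential_reactions(m, "t", "c", epsilon=1e-6)
        assert np.allclose(fwd["log2FC"], -rev["log2FC"])
        assert np.allclose(fwd["t"], -rev["t"])
        assert np.allclose(fwd["p"], rev["p"])
        assert len(fwd) == len(m)

    def test_too_few_replicates_raises(self):
        m = flux_matrix({"r": [1.0, 4.0, 5.0, 6.0]}, ctrl=("c", 1), treat=("t", 3))
        with pytest.raises(ValueError, match="replicates"):
            differential_reactions(m, "c", "t")


@pytest.fixture
def producer_consumer_network():
    return MetabolicNetwork(
        metabolites=(MetaboliteRecord(id="M", compartment="c"),),
        reactions=(
            ReactionRecord(id="make", stoichiometry={"M": 2.0}, lower_bound=0.0,
                           upper_bound=10.0),
            ReactionRecord(id="use", stoichiometry={"M": -1.0}, lower_bound=0.0,
                           upper_bound=10.0),
        ),
        objective_id="use",
    )


class TestMetaboliteTurnover:
    def test_positive_part_sum(self, producer_consumer_network):
        m = flux_matrix({"make": [3.0] * 6, "use": [6.0] * 6})
        t = metabolite_turnover(producer_consumer_network, m)
        # producer contributes S=+2 x v=3 = 6; consumer's negative part ignored
        assert (t.loc["M"] == 6.0).all()

    def test_all_zero_column(self, producer_consumer_network):
        m = flux_matrix({"make": [0.0] * 6, "use": [0.0] * 6})
        t = metabolite_turnover(producer_consumer_network, m)
        assert (t.loc["M"] == 0.0).all()

    def test_unknown_reaction_raises(self, producer_consumer_network):
        m = flux_matrix({"mystery": [1.0] * 6})
        with pytest.raises(ValueError, match="mystery"):
            metabolite_turnover(producer_consumer_network, m)

    def test_both_zero_turnover_differential(self, producer_consumer_network):
        m = flux_matrix({"make": [0.0] * 6, "use": [0.0] * 6})
        row = differential_metabolites(producer_consumer_network, m, "c", "t").iloc[0]
        assert row["log2FC"] == 0.0 and row["p"] == 1.0

    def test_antisymmetry_under_label_swap(self, producer_consumer_network):
        m = flux_matrix({"make": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], "use": [2.0] * 6})
        fwd = differential_metabolites(producer_consumer_network, m, "c", "t")
        rev = differential_metabolites(producer_consumer_network, m, "t", "c")
        assert np.allclose(fwd["log2FC"], -rev["log2FC"])
        assert np.allclose(fwd["p"], rev["p"])


class TestSubsystemEnrichment:
    def _background_network(self, subsystem_of):
        mets = (MetaboliteRecord(id="X", compartment="c"),)
        rxns = tuple(
            ReactionRecord(id=rid, stoichiometry={"X": 1.0}, lower_bound=0.0,
                           upper_bound=1.0, subsystem=sub)
            for rid, sub in subsystem_of.items()
        )
        return MetabolicNetwork(metabolites=mets, reactions=rxns,
                                objective_id=next(iter(subsystem_of)))

    def test_hand_table_matches_fisher_example(self):
        # 8 reactions, subsystem of 4, significant set of 4 with overlap 3
        subsystem_of = {f"r{i}": ("inA" if i < 4 else "out") for i in range(8)}
        net = self._background_network(subsystem_of)
        diff = pd.DataFrame({
            "feature_id": [f"r{i}" for i in range(8)],
            "p_adj": [0.01, 0.01, 0.01, 0.9, 0.01, 0.9, 0.9, 0.9],
        })
        enr = subsystem_enrichment(diff, net).set_index("subsystem")
        assert enr.loc["inA", "p"] == pytest.approx(17 / 70, abs=1e-12)
        row = enr.loc["inA"]
        assert row[["k_sig_in", "k_sig_out", "k_nonsig_in", "k_nonsig_out"]].sum() == 8

    def test_no_significant_reactions_all_p_one(self):
        subsystem_of = {f"r{i}": f"s{i % 2}" for i in range(6)}
        net = self._background_network(subsystem_of)
        diff = pd.DataFrame({"feature_id": list(subsystem_of), "p_adj": [0.9] * 6})
        enr = subsystem_enrichment(diff, net)
        assert (enr["p"] == 1.0).all()

    def test_counts_conserve_background(self):
        rng = np.random.default_rng(3)
        subsystem_of = {f"r{i}": f"s{rng.integers(4)}" for i in range(30)}
        net = self._background_network(subsystem_of)
        diff = pd.DataFrame({
            "feature_id": list(subsystem_of),
            "p_adj": rng.uniform(0, 1, 30),
        })
        enr = subsystem_enrichment(diff, net, alpha=0.3)
        counts = enr[["k_sig_in", "k_sig_out", "k_nonsig_in", "k_nonsig_out"]].sum(axis=1)
        assert (counts == 30).all()

    def test_incomplete_table_raises(self):
        net = self._background_network({"r0": "s", "r1": "s"})
        diff = pd.DataFrame({"feature_id": ["r0"], "p_adj": [0.01]})
        with pytest.raises(ValueError, match="cover"):
            subsystem_enrichment(diff, net)


def test_fisher_greater_matches_bruteforce_small_tables():
    """Spot-check the hypergeometric tail against direct summation."""
    for a in range(0, 6):
        for b in range(0, 4):
            for c in range(0, 4):
                for d in range(0, 4):
                    if a + b + c + d == 0:
                        continue
                    assert fisher_exact_2x2(a, b, c, d, "greater") == pytest.approx(
                        hypergeom_tail_bruteforce(a, b, c, d), abs=1e-12
                    )
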