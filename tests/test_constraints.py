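"""Model-construction operations: GPR aggregation, capacity, thermo, medium."""

import numpy as np
import pytest

from lipoflux.constraints import (
    ConstraintConfig,
    ExpressionProfile,
    MediumTable,
    aggregate_gpr_abundance,
    apply_medium,
    capacity_bounds,
    read_config,
    thermodynamic_directions,
)
from lipoflux.fba import solve_fba
from lipoflux.gpr import parse_gpr
from lipoflux.network import ReactionRecord
from lipoflux.synth import ToyNetworkSpec, make_expression_replicates, make_toy_network, \
    default_medium, PlantedEffect


def profile(values):
    return ExpressionProfile(condition="c", replicate="r", values=values)


class TestAggregation:
    @pytest.mark.parametrize(
        "rule,values,expected",
        [
            ("G1 and G2", {"G1": 3, "G2": 5}, 3),        # complex: scarcest subunit
            ("G1 or G2", {"G1": 3, "G2": 5}, 8),         # isoenzymes add
            ("G1 or GX", {"G1": 3}, 3),                  # missing gene contributes 0
            ("G1 and GX", {"G1": 3}, 0),
            ("(G1 and G2) or G3", {"G1": 2, "G2": 7, "G3": 1}, 3),
        ],
    )
    def test_rules(self, rule, values, expected):
        assert aggregate_gpr_abundance(parse_gpr(rule), profile(values)) == expected

    def test_empty_tree_is_absent(self):
        assert aggregate_gpr_abundance(parse_gpr(""), profile({"G1": 3})) is None

    def test_monotone_in_gene_abundance(self):
        rng = np.random.default_rng(4)
        rules = ["G1 and (G2 or G3)", "(G1 or G2) and G3", "G1 or G2 or G3", "G1 and G2 and G3"]
        for _ in range(50):
            rule = rules[rng.integers(len(rules))]
            vals = {g: float(rng.uniform(0, 10)) for g in ("G1", "G2", "G3")}
            base = aggregate_gpr_abundance(parse_gpr(rule), profile(vals))
            bumped = dict(vals)
            gene = ("G1", "G2", "G3")[rng.integers(3)]
            bumped[gene] += float(rng.uniform(0, 5))
            assert aggregate_gpr_abundance(parse_gpr(rule), profile(bumped)) >= base


class TestCapacityBounds:
    def _one_reaction_net(self, lb):
        from lipoflux.network import MetabolicNetwork, MetaboliteRecord

        return MetabolicNetwork(
            metabolites=(MetaboliteRecord(id="A", compartment="c"),),
            reactions=(
                ReactionRecord(
                    id="R", stoichiometry={"A": 1.0}, lower_bound=lb, upper_bound=1000.0,
                    gpr=parse_gpr("G1"), kcat=2.0,
                ),
            ),
            objective_id="R",
        )

    def test_cap_applied_to_upper_bound(self):
        net = self._one_reaction_net(lb=0.0)
        out = capacity_bounds(net, profile({"G1": 3.0}), ConstraintConfig(capacity_scale=1.0))
        assert out.reaction("R").upper_bound == 6.0
        assert out.reaction("R").lower_bound == 0.0

    def test_reversible_gets_symmetric_bound(self):
        net = self._one_reaction_net(lb=-1000.0)
        out = capacity_bounds(net, profile({"G1": 3.0}))
        assert out.reaction("R").lower_bound == -6.0

    def test_missing_kcat_untouched(self, toy_network, flat_profile):
        stripped = toy_network.with_reactions(
            [ReactionRecord(**{**r.__dict__, "kcat": None}) for r in toy_network.reactions]
        )
        out = capacity_bounds(stripped, flat_profile)
        assert [(r.lower_bound, r.upper_bound) for r in out.reactions] == [
            (r.lower_bound, r.upper_bound) for r in stripped.reactions
        ]

    def test_pure_and_idempotent(self, toy_network, flat_profile):
        before = toy_network.reactions
        once = capacity_bounds(toy_network, flat_profile)
        assert toy_network.reactions == before  # input untouched
        twice = capacity_bounds(once, flat_profile)
        assert twice.reactions == once.reactions

    def test_never_widens_bounds(self):
        rng = np.random.default_rng(9)
        for seed in range(10):
            net = make_toy_network(ToyNetworkSpec(n_subsystems=2, seed=seed))
            prof = profile({g: float(rng.uniform(0, 5)) for g in net.genes()})
            out = capacity_bounds(net, prof)
            for a, b in zip(net.reactions, out.reactions):
                assert b.lower_bound >= a.lower_bound
                assert b.upper_bound <= a.upper_bound


class TestThermodynamicDirections:
    def _net_with_dg(self, dg, lb=-1000.0, ub=1000.0):
        from lipoflux.network import MetabolicNetwork, MetaboliteRecord

        return MetabolicNetwork(
            metabolites=(MetaboliteRecord(id="A", compartment="c"),),
            reactions=(
                ReactionRecord(id="R", stoichiometry={"A": 1.0}, lower_bound=lb,
                               upper_bound=ub, delta_g_prime=dg),
            ),
            objective_id="R",
        )

    @pytest.mark.parametrize(
        "dg,expected",
        [
            (-25.0, (0.0, 1000.0)),    # strongly exergonic: forward-only
            (25.0, (-1000.0, 0.0)),    # strongly endergonic: reverse-only
            (-5.0, (-1000.0, 1000.0)),  # inside the +-tau dead band
            (None, (-1000.0, 1000.0)),
        ],
    )
    def test_sign_rule(self, dg, expected):
        out = thermodynamic_directions(self._net_with_dg(dg), ConstraintConfig(thermo_threshold=10))
        r = out.reaction("R")
        assert (r.lower_bound, r.upper_bound) == expected

    def test_conflict_collapses_to_zero_with_warning(self):
        net = self._net_with_dg(25.0, lb=1.0, ub=5.0)  # forced forward but endergonic
        with pytest.warns(UserWarning, match="collapsing"):
            out = thermodynamic_directions(net)
        assert (out.reaction("R").lower_bound, out.reaction("R").upper_bound) == (0.0, 0.0)

    def test_idempotent(self, toy_network):
        once = thermodynamic_directions(toy_network)
        twice = thermodynamic_directions(once)
        assert twice.reactions == once.reactions


class TestMedium:
    def test_uptake_sets_negative_lower_bound(self, chain_network):
        out = apply_medium(chain_network, MediumTable(entries={"A": 10.0}))
        assert out.reaction("EX_A").lower_bound == -10.0

    def test_absent_metabolite_blocks_uptake(self, chain_network):
        out = apply_medium(chain_network, MediumTable(entries={}))
        assert out.reaction("EX_A").lower_bound == 0.0

    def test_empty_medium_kills_growth(self, toy_network):
        out = apply_medium(toy_network, MediumTable(entries={}))
        sol = solve_fba(out)
        assert sol.optimal and sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_missing_exchange_warns(self, chain_network):
        with pytest.warns(UserWarning, match="ghost"):
            apply_medium(chain_network, MediumTable(entries={"A": 10.0, "ghost": 1.0}))

    def test_secretion_untouched(self, chain_network):
        out = apply_medium(chain_network, MediumTable(entries={"A": 10.0}))
        assert out.reaction("EX_A").upper_bound == 1000.0


def test_config_file_roundtrip(tmp_path):
    path = tmp_path / "config.txt"
    path.write_text("capacity_scale = 2.5\nthermo_threshold=4\n# comment\ndefault_uptake = 7\n")
    cfg = read_config(path)
    assert cfg == ConstraintConfig(capacity_scale=2.5, thermo_threshold=4.0, default_uptake=7.0)


def test_planted_expression_effect_log_ratio():
    """A planted 4-fold effect shows up as ~2 on the mean log2 ratio."""
    net = make_toy_network(ToyNetworkSpec(seed=3))
    effect = PlantedEffect(target="subsystem_1", effect_size=4.0, noise_sd=0.1, seed=5)
    profiles = make_expression_replicates(net, effect)
    targets = sorted(
        g for r in net.reactions if r.subsystem == "subsystem_1"
        for g in [r.gpr.gene] if r.gpr.kind == "gene"
    )
    ctrl = [p for p in profiles if p.condition == "UCM"]
    treat = [p for p in profiles if p.condition == "ACM"]
    ratios = [
        np.log2(t.values[g] / c.values[g])
        for g in targets for c, t in zip(ctrl, treat)
    ]
    n = len(ratios)
    # tolerance 3*sd/sqrt(n) on the mean of log2 ratios (sd of a log2 ratio
    # of two lognormals with log-sd 0.1 is 0.1*sqrt(2)/ln2)
    tol = 3 * (0.1 * np.sqrt(2) / np.log(2)) / np.sqrt(n)
    assert np.mean(ratios) == pytest.approx(2.0, abs=tol)
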