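"""Filter families: property, similarity (cutoff + sampling), metabolomics,
thermodynamics, feasibility, and the target-efficiency statistic."""

import numpy as np
import pytest

from rulenet.chem_core import Reaction, standardize_compound
from rulenet.filters import (
    AdductSpec,
    AlwaysFeasiblePredictor,
    CompoundPropertyFilterConfig,
    ConstantDGProvider,
    DenyListPredictor,
    EfficiencyRecord,
    FeasibilityFilter,
    FilterStack,
    MetabolomicsFilter,
    MetabolomicsFilterConfig,
    NullDGProvider,
    PropertyFilter,
    SimilarityCutoffFilter,
    ThermoConditions,
    ThermodynamicsFilter,
    default_adducts,
    feasibility_filter,
    max_similarity_scores,
    metabolomics_filter,
    mz_candidates,
    property_filter,
    similarity_cutoff_filter,
    similarity_sample_filter,
    target_efficiency,
    thermodynamics_filter,
)


def _comp(smiles, **kw):
    return standardize_compound(smiles, **kw)


class TestPropertyFilter:
    def test_carbon_ceiling(self):
        c12 = _comp("CCCCCCCCCCCC")
        c11 = _comp("CCCCCCCCCCC")
        cfg = CompoundPropertyFilterConfig(element_ranges={"C": (0, 11)})
        assert property_filter([c12, c11], cfg) == {c12.cid}

    def test_mw_bounds(self):
        heavy = _comp("C" * 50)  # ~701 Da
        light = _comp("CCO")
        cfg = CompoundPropertyFilterConfig(mw_max=600.0)
        assert property_filter([heavy, light], cfg) == {heavy.cid}
        cfg = CompoundPropertyFilterConfig(mw_min=100.0)
        assert property_filter([light], cfg) == {light.cid}

    def test_empty_config_flags_nothing(self):
        cfg = CompoundPropertyFilterConfig()
        assert property_filter([_comp("CCO"), _comp("C" * 50)], cfg) == set()

    def test_cofactor_exemption(self):
        water = _comp("O", is_cofactor=True)
        cfg = CompoundPropertyFilterConfig(mw_min=100.0)
        assert property_filter([water], cfg) == set()
        cfg = CompoundPropertyFilterConfig(mw_min=100.0,
                                           exempt_cofactors=False)
        assert property_filter([water], cfg) == {water.cid}

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            CompoundPropertyFilterConfig(mw_min=10, mw_max=5)


class TestSimilarityScores:
    def test_member_of_target_set_scores_one(self):
        ethanol = _comp("CCO")
        scores = max_similarity_scores([ethanol], [ethanol, _comp("CC=O")])
        assert scores[ethanol.cid] == 1.0

    def test_disjoint_fingerprints_score_zero(self):
        methane = _comp("C")  # no bond paths -> empty fingerprint
        scores = max_similarity_scores([methane], [_comp("CCO")])
        assert scores[methane.cid] == 0.0

    def test_pinned_regression_pair(self):
        # frozen from an independent fingerprint run (2048-bit path fp)
        scores = max_similarity_scores([_comp("CCO")], [_comp("CC(=O)O")])
        assert list(scores.values())[0] == pytest.approx(3 / 7, abs=1e-9)

    def test_symmetry_and_range(self):
        pool = [_comp(s) for s in ["CCO", "CC(=O)O", "c1ccccc1O", "NCC(=O)O"]]
        for a in pool:
            for b in pool:
                sa = max_similarity_scores([a], [b])[a.cid]
                sb = max_similarity_scores([b], [a])[b.cid]
                assert sa == pytest.approx(sb) and 0.0 <= sa <= 1.0

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            max_similarity_scores([_comp("CCO")], [])


class TestSimilarityCutoff:
    def test_strict_below_convention(self):
        scores = {"a": 0.59, "b": 0.60, "c": 0.61}
        assert similarity_cutoff_filter(scores, 0.6) == {"a"}

    def test_zero_cutoff_flags_nothing(self):
        assert similarity_cutoff_filter({"a": 0.0, "b": 0.5}, 0.0) == set()

    def test_unit_cutoff_keeps_exact_matches_only(self):
        assert similarity_cutoff_filter({"a": 1.0, "b": 0.999}, 1.0) == {"b"}

    def test_reached_targets_exempt(self):
        assert similarity_cutoff_filter({"t": 0.1}, 0.9, exempt={"t"}) == set()

    def test_cutoff_out_of_range(self):
        with pytest.raises(ValueError):
            similarity_cutoff_filter({}, 1.5)


class TestSimilaritySampler:
    def test_pool_smaller_than_sample_kept_whole(self):
        scores = {"a": 0.1, "b": 0.2}
        assert similarity_sample_filter(scores, 5, 3.0, seed=0) == {"a", "b"}

    def test_deterministic_under_seed(self):
        scores = {f"c{i}": (i + 1) / 20 for i in range(20)}
        picks = [similarity_sample_filter(scores, 5, 3.0, seed=42)
                 for _ in range(3)]
        assert picks[0] == picks[1] == picks[2]

    def test_uniform_frequencies_k0(self):
        scores = {"a": 0.1, "b": 0.5, "c": 0.9}
        counts = {c: 0 for c in scores}
        for rep in range(10000):
            (picked,) = similarity_sample_filter(scores, 1, 0.0, seed=rep)
            counts[picked] += 1
        p = 1 / 3
        sigma = np.sqrt(10000 * p * (1 - p))
        for c in counts.values():
            assert abs(c - 10000 * p) <= 3 * sigma

    def test_weight_ratio_k3(self):
        # weights 0.2^3 : 0.4^3 = 1 : 8 -> P(low) = 1/9
        scores = {"low": 0.2, "high": 0.4}
        n_low = sum(
            "low" in similarity_sample_filter(scores, 1, 3.0, seed=rep)
            for rep in range(10000)
        )
        p = 1 / 9
        sigma = np.sqrt(10000 * p * (1 - p))
        assert abs(n_low - 10000 * p) <= 3 * sigma

    def test_zero_weights_fall_back_to_uniform(self):
        scores = {"a": 0.0, "b": 0.0, "c": 0.0}
        kept = similarity_sample_filter(scores, 2, 3.0, seed=1)
        assert len(kept) == 2

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            similarity_sample_filter({"a": 0.5}, 0, 1.0, seed=0)
        with pytest.raises(ValueError):
            similarity_sample_filter({"a": 0.5}, 1, -1.0, seed=0)


class TestMzCandidates:
    def test_glycine_protonated(self):
        (name, mz), = mz_candidates(_comp("NCC(=O)O"),
                                    [AdductSpec("[M+H]+", 1.007276466, 1)])
        assert mz == pytest.approx(76.039305, abs=1e-5)

    def test_acetic_acid_deprotonated(self):
        (_, mz), = mz_candidates(_comp("CC(=O)O"),
                                 [AdductSpec("[M-H]-", -1.007276466, -1)])
        assert mz == pytest.approx(59.013853, abs=1e-5)

    def test_dimer_adduct(self):
        (_, mz), = mz_candidates(_comp("NCC(=O)O"),
                                 [AdductSpec("[2M+H]+", 1.007276466, 1, 2)])
        assert mz == pytest.approx(151.071333, abs=1e-5)

    def test_empty_adducts_empty_result(self):
        assert mz_candidates(_comp("CCO"), []) == []

    def test_invalid_adducts_rejected(self):
        with pytest.raises(ValueError):
            AdductSpec("bad", 0.0, 0)
        with pytest.raises(ValueError):
            AdductSpec("bad", 0.0, 1, 0)


class TestMetabolomicsFilter:
    def test_matching_compound_kept(self):
        glycine, alanine = _comp("NCC(=O)O"), _comp("CC(N)C(=O)O")
        cfg = MetabolomicsFilterConfig(
            peaks=[76.0393], adducts=[AdductSpec("[M+H]+", 1.007276466, 1)],
            tolerance=0.005)
        kept, pairs = metabolomics_filter([glycine, alanine], cfg)
        assert kept == {glycine.cid}
        assert all(cid == glycine.cid for cid, *_ in pairs)

    def test_empty_peaks_rejected_at_construction(self):
        with pytest.raises(ValueError):
            MetabolomicsFilterConfig(peaks=[], adducts=default_adducts())

    def test_tolerance_bound_inclusive(self):
        glycine = _comp("NCC(=O)O")
        adduct = AdductSpec("[M+H]+", 1.007276466, 1)
        mz = adduct.mz(glycine.mono_mass)
        peak = mz + 0.003
        cfg = MetabolomicsFilterConfig(peaks=[peak], adducts=[adduct],
                                       tolerance=abs(mz - peak))
        kept, _ = metabolomics_filter([glycine], cfg)
        assert kept == {glycine.cid}

    def test_ppm_tolerance(self):
        glycine = _comp("NCC(=O)O")
        adduct = AdductSpec("[M+H]+", 1.007276466, 1)
        mz = adduct.mz(glycine.mono_mass)
        cfg = MetabolomicsFilterConfig(peaks=[mz * (1 + 4e-6)],
                                       adducts=[adduct],
                                       tolerance=5, tolerance_unit="ppm")
        kept, _ = metabolomics_filter([glycine], cfg)
        assert kept == {glycine.cid}
        cfg = MetabolomicsFilterConfig(peaks=[mz * (1 + 6e-6)],
                                       adducts=[adduct],
                                       tolerance=5, tolerance_unit="ppm")
        kept, pairs = metabolomics_filter([glycine], cfg)
        assert kept == set() and pairs == []

    def test_pair_table_entries_within_tolerance(self):
        pool = [_comp(s) for s in ["CCO", "NCC(=O)O", "CC(=O)O", "CCC=O"]]
        cfg = MetabolomicsFilterConfig(
            peaks=[47.0491, 76.0393, 61.0284], adducts=default_adducts(),
            tolerance=0.01)
        kept, pairs = metabolomics_filter(pool, cfg)
        assert kept == {cid for cid, *_ in pairs}
        for _, _, peak, mz in pairs:
            assert abs(mz - peak) <= 0.01


class TestThermodynamicsFilter:
    def _rxn(self, rid="Rx"):
        return Reaction(rid, [(1, "Ca")], [(1, "Cb")], "op")

    def test_over_limit_removed(self):
        cond = ThermoConditions(dg_max=50.0)
        provider = ConstantDGProvider({"Rx": 60.0})
        assert thermodynamics_filter([self._rxn()], provider, cond) == set()

    def test_unknown_dg_retained(self):
        cond = ThermoConditions(dg_max=50.0)
        assert thermodynamics_filter([self._rxn()], NullDGProvider(),
                                     cond) == {"Rx"}

    def test_boundary_inclusive(self):
        cond = ThermoConditions(dg_max=50.0)
        provider = ConstantDGProvider({"Rx": 50.0})
        assert thermodynamics_filter([self._rxn()], provider, cond) == {"Rx"}

    def test_provider_failure_fails_open(self):
        class Boom:
            def dg(self, reaction, registry, conditions):
                raise RuntimeError("no estimate")

        cond = ThermoConditions(dg_max=50.0)
        assert thermodynamics_filter([self._rxn()], Boom(), cond) == {"Rx"}

    def test_physiological_mode_pins_conditions(self):
        cond = ThermoConditions(mode="physiological", pH=3.0,
                                ionic_strength=1.0, concentration=1.0)
        assert (cond.pH, cond.ionic_strength, cond.concentration) == \
            (7.5, 0.25, 1e-3)


class TestFeasibilityFilter:
    @staticmethod
    def _pair_setup():
        ester, water = _comp("CCOC(C)=O"), _comp("O", is_cofactor=True)
        acid, alcohol = _comp("CC(=O)O"), _comp("CCO")
        registry = {c.cid: c for c in (ester, water, acid, alcohol)}
        rxn = Reaction("Rh", [(1, ester.cid), (1, water.cid)],
                       [(1, acid.cid), (1, alcohol.cid)], "thy01")
        return registry, rxn, ester, acid

    def test_always_feasible_keeps_all(self):
        registry, rxn, *_ = self._pair_setup()
        assert feasibility_filter([rxn], AlwaysFeasiblePredictor(),
                                  registry) == {"Rh"}

    def test_deny_list_removes_exactly_that_reaction(self):
        registry, rxn, ester, acid = self._pair_setup()
        # principal pair: largest non-cofactor substrate (ester) and
        # largest non-cofactor product (acid, 4 heavy atoms vs ethanol's 3)
        predictor = DenyListPredictor({(ester.smiles, acid.smiles)})
        assert feasibility_filter([rxn], predictor, registry) == set()
        other = Reaction("Ro", [(1, ester.cid)], [(1, ester.cid)], "op")
        assert feasibility_filter([rxn, other], predictor,
                                  registry) == {"Ro"}

    def test_predictor_failure_fails_open(self):
        class Boom:
            def feasible(self, substrate, product):
                raise RuntimeError("model unavailable")

        registry, rxn, *_ = self._pair_setup()
        assert feasibility_filter([rxn], Boom(), registry) == {"Rh"}


class TestComposition:
    def test_post_filters_intersect_order_independent(self):
        pool = [_comp(s) for s in
                ["CCO", "NCC(=O)O", "CC(=O)O", "CCCCCCCCCCCC", "CCC=O"]]
        compounds = {c.cid: c for c in pool}
        rxns = {
            f"R{i}": Reaction(f"R{i}", [(1, pool[i].cid)],
                              [(1, pool[i + 1].cid)], "op")
            for i in range(len(pool) - 1)
        }

        def build_stack(order):
            prop = PropertyFilter(CompoundPropertyFilterConfig(
                element_ranges={"C": (0, 11)}))
            thermo = ThermodynamicsFilter(
                ConstantDGProvider({"R1": 80.0}, default=10.0),
                ThermoConditions(dg_max=50.0))
            feas = FeasibilityFilter(
                DenyListPredictor({(pool[2].cid and pool[2].smiles,
                                    pool[3].smiles)}))
            filters = {"p": prop, "t": thermo, "f": feas}
            return [filters[k] for k in order]

        results = []
        for order in ("ptf", "ftp", "tfp"):
            flagged_c, flagged_r = set(), set()
            for f in build_stack(order):
                d = f(compounds, rxns, compounds)
                flagged_c |= d.flagged_compounds
                flagged_r |= d.flagged_reactions
            results.append((frozenset(flagged_c), frozenset(flagged_r)))
        assert len(set(results)) == 1
        # and the union of flags equals the complement of survivor intersection
        flagged_c, flagged_r = results[0]
        assert flagged_r  # thermo and feasibility each flagged something
        assert flagged_c  # the C12 compound


class TestTargetEfficiency:
    def test_identical_ratios(self):
        rec = EfficiencyRecord(10, 100, 10, 100)
        assert target_efficiency(rec) == pytest.approx(1.0)

    def test_doubled_ratio(self):
        rec = EfficiencyRecord(10, 100, 5, 100)
        assert target_efficiency(rec) == pytest.approx(2.0)

    def test_zero_targets(self):
        rec = EfficiencyRecord(0, 100, 5, 100)
        assert target_efficiency(rec) == 0.0

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            target_efficiency(EfficiencyRecord(1, 0, 5, 100))
        with pytest.raises(ValueError):
            target_efficiency(EfficiencyRecord(1, 10, 0, 100))
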