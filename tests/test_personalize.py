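import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boolomics.logic import parse_rules
from boolomics.personalize import (
    ForcingPolicy,
    MutationCall,
    PatientProfile,
    apply_discrete_forcings,
    build_personalized_model,
    cohort_profiles,
    derive_rates_and_initial,
    discretize_lrr,
    discretize_lrr_frame,
    normalize_expression,
    read_cnv,
    read_expression,
    read_metadata,
    read_mutations,
)
from boolomics.simulate import SimulationConfig, exact_master_equation

finite_lrr = st.floats(min_value=-5, max_value=5, allow_nan=False, allow_infinity=False)


class TestDiscretizeLrr:
    @pytest.mark.parametrize(
        "lrr,expected",
        [
            (-1.2, -2),
            (-1.1, -2),
            (-1.0999, -1),
            (-0.2, -1),
            (0.0, 0),
            (0.2, 0),
            (0.7, 1),  # inclusive upper boundary of the single-gain class
            (0.70001, 2),
            (0.8, 2),
        ],
    )
    def test_printed_thresholds(self, lrr, expected):
        assert discretize_lrr(lrr) == expected

    def test_non_finite_rejected(self):
        for bad in (float("nan"), float("inf")):
            with pytest.raises(ValueError, match="finite"):
                discretize_lrr(bad)

    @settings(max_examples=200, deadline=None)
    @given(a=finite_lrr, b=finite_lrr)
    def test_monotone_step_function(self, a, b):
        lo, hi = sorted((a, b))
        assert discretize_lrr(lo) <= discretize_lrr(hi)
        assert discretize_lrr(a) in (-2, -1, 0, 1, 2)

    def test_matrix_discretization_matches_scalar(self):
        df = pd.DataFrame({"s1": [-1.2, 0.7], "s2": [0.8, -0.3]}, index=["g1", "g2"])
        out = discretize_lrr_frame(df)
        for g in df.index:
            for s in df.columns:
                assert out.loc[g, s] == discretize_lrr(df.loc[g, s])


class TestNormalizeExpression:
    def test_minmax_by_definition(self):
        df = pd.DataFrame([[10.0, 20.0, 30.0]], index=["g"], columns=list("abc"))
        out = normalize_expression(df)
        assert out.loc["g"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_gene_maps_to_half(self):
        df = pd.DataFrame([[7.0, 7.0, 7.0]], index=["g"], columns=list("abc"))
        assert normalize_expression(df).loc["g"].tolist() == [0.5, 0.5, 0.5]

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="cohort"):
            normalize_expression(pd.DataFrame([[1.0]], index=["g"], columns=["a"]))

    def test_negative_values_rejected(self):
        df = pd.DataFrame([[-1.0, 2.0]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError, match="non-negative"):
            normalize_expression(df)

    def test_minmax_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(rng.uniform(1, 100, size=(4, 8)))
        scaled = raw * 3.5 + 11.0
        pd.testing.assert_frame_equal(
            normalize_expression(raw), normalize_expression(scaled), atol=1e-12
        )

    def test_rank_method_preserves_sample_ranks(self):
        """Monotone transform of inputs leaves rank-normalized outputs unchanged."""
        from scipy.stats import rankdata

        rng = np.random.default_rng(1)
        raw = pd.DataFrame(rng.uniform(1, 50, size=(3, 9)))
        out = normalize_expression(raw, method="rank")
        pd.testing.assert_frame_equal(
            out, normalize_expression(raw**2, method="rank"), atol=1e-12
        )
        for i in range(3):
            expected = (rankdata(raw.iloc[i]) - 1) / 8
            np.testing.assert_allclose(out.iloc[i], expected)


@pytest.fixture()
def small_net():
    return parse_rules("TP53, TP53\nMYC, !TP53\nAR_ERG, MYC")


class TestForcings:
    def test_inactivating_mutation_forces_zero(self, small_net):
        prof = PatientProfile(
            "s", "AA", mutations=(MutationCall("TP53", "inactivating", "s"),)
        )
        assert apply_discrete_forcings(prof, small_net) == {"TP53": 0}

    def test_amplification_forces_one(self, small_net):
        prof = PatientProfile("s", "AA", ploidy={"MYC": 2})
        assert apply_discrete_forcings(prof, small_net) == {"MYC": 1}

    def test_unknown_effect_and_single_copy_changes_do_nothing(self, small_net):
        prof = PatientProfile(
            "s", "AA",
            mutations=(MutationCall("TP53", "unknown", "s"),),
            ploidy={"MYC": 1, "TP53": -1},
        )
        assert apply_discrete_forcings(prof, small_net) == {}

    def test_mutation_beats_deep_deletion_by_default(self, small_net, caplog):
        prof = PatientProfile(
            "s", "AA",
            mutations=(MutationCall("MYC", "activating", "s"),),
            ploidy={"MYC": -2},
        )
        with caplog.at_level("WARNING", logger="boolomics.personalize"):
            forced = apply_discrete_forcings(prof, small_net)
        assert forced == {"MYC": 1}
        assert any("conflicting" in r.message for r in caplog.records)

    def test_cnv_precedence_flips_the_winner(self, small_net):
        prof = PatientProfile(
            "s", "AA",
            mutations=(MutationCall("MYC", "activating", "s"),),
            ploidy={"MYC": -2},
        )
        policy = ForcingPolicy(precedence="cnv")
        assert apply_discrete_forcings(prof, small_net, policy) == {"MYC": 0}

    def test_strict_policy_raises_on_conflict(self, small_net):
        prof = PatientProfile(
            "s", "AA",
            mutations=(MutationCall("MYC", "activating", "s"),),
            ploidy={"MYC": -2},
        )
        with pytest.raises(ValueError, match="conflicting"):
            apply_discrete_forcings(prof, small_net, ForcingPolicy(strict=True))

    def test_conflicting_mutation_effects_cancel_unless_strict(self, small_net):
        prof = PatientProfile(
            "s", "AA",
            mutations=(
                MutationCall("TP53", "activating", "s"),
                MutationCall("TP53", "inactivating", "s"),
            ),
        )
        assert apply_discrete_forcings(prof, small_net) == {}
        with pytest.raises(ValueError, match="conflicting mutation effects"):
            apply_discrete_forcings(prof, small_net, ForcingPolicy(strict=True))

    def test_genes_absent_from_network_are_ignored(self, small_net):
        prof = PatientProfile(
            "s", "AA", mutations=(MutationCall("KRAS", "activating", "s"),)
        )
        assert apply_discrete_forcings(prof, small_net) == {}

    def test_fusion_node_is_never_forced_by_default(self, small_net):
        prof = PatientProfile("s", "AA", ploidy={"AR_ERG": 2})
        assert apply_discrete_forcings(prof, small_net) == {}

    def test_alias_table_maps_gene_to_node(self, small_net):
        prof = PatientProfile(
            "s", "AA", mutations=(MutationCall("MYC_PROBE", "activating", "s"),)
        )
        forced = apply_discrete_forcings(
            prof, small_net, aliases={"MYC_PROBE": "MYC"}
        )
        assert forced == {"MYC": 1}


class TestRatesAndInitial:
    def test_symmetric_midpoint(self, small_net):
        prof = PatientProfile("s", "AA", expression={"TP53": 0.5})
        rates, init = derive_rates_and_initial(prof, small_net, scale=2.0)
        assert rates.up["TP53"] == rates.down["TP53"] == 1.0
        assert init["TP53"] == 0.5

    def test_extreme_expression_clamped(self, small_net):
        prof = PatientProfile("s", "AA", expression={"TP53": 1.0})
        rates, init = derive_rates_and_initial(prof, small_net)
        assert rates.up["TP53"] == pytest.approx(0.99)
        assert rates.down["TP53"] == pytest.approx(0.01)

    def test_missing_gene_gets_defaults(self, small_net):
        prof = PatientProfile("s", "AA", expression={"TP53": 0.8})
        rates, init = derive_rates_and_initial(prof, small_net)
        assert rates.up["MYC"] == rates.down["MYC"] == 0.5
        assert init["MYC"] == 0.5

    def test_nonpositive_scale_rejected(self, small_net):
        with pytest.raises(ValueError, match="positive"):
            derive_rates_and_initial(PatientProfile("s", "AA"), small_net, scale=0.0)

    def test_input_free_node_holds_its_initial_probability(self):
        """A self-sustaining node never flips, so activity stays at x."""
        net = parse_rules("A, A")
        prof = PatientProfile("s", "AA", expression={"A": 0.73})
        model = build_personalized_model(prof, net)
        curve = exact_master_equation(model, SimulationConfig(t_max=20, n_grid=21))["A"]
        np.testing.assert_allclose(curve.activity, 0.73, atol=1e-12)


class TestBuildModel:
    def test_neutral_patient_gets_uniform_defaults(self, small_net):
        model = build_personalized_model(PatientProfile("s", "AA"), small_net)
        assert model.forcings == {}
        assert all(v == 0.5 for v in model.rates.up.values())
        assert all(v == 0.5 for v in model.initial_p_on.values())

    def test_forcing_overrides_rates_and_initial(self, small_net):
        prof = PatientProfile(
            "s", "AA",
            mutations=(MutationCall("TP53", "inactivating", "s"),),
            expression={"TP53": 0.9},
        )
        model = build_personalized_model(prof, small_net)
        assert model.forcings == {"TP53": 0}
        assert "TP53" not in model.rates.up
        assert model.initial_p_on["TP53"] == 0.0

    def test_forced_node_simulates_constant(self, toy_net):
        prof = PatientProfile("s", "AA", ploidy={"AR": 2})
        model = build_personalized_model(prof, toy_net)
        curve = exact_master_equation(model, SimulationConfig(t_max=10, n_grid=11))["AR"]
        assert np.all(curve.activity == 1.0)

    def test_identical_profiles_build_identical_models(self, small_net):
        prof = PatientProfile("s", "AA", expression={"TP53": 0.4, "MYC": 0.6})
        m1 = build_personalized_model(prof, small_net)
        m2 = build_personalized_model(prof, small_net)
        assert m1.rates.up == m2.rates.up and m1.initial_p_on == m2.initial_p_on


class TestCohortAssembly:
    def _tables(self, tmp_path):
        (tmp_path / "mut.tsv").write_text(
            "sample\tgene\teffect\ns1\tTP53\tinactivating\n"
        )
        (tmp_path / "cnv.tsv").write_text("gene\ts1\ts2\nMYC\t0.9\t0.0\n")
        (tmp_path / "expr.tsv").write_text("gene\ts1\ts2\nTP53\t10\t30\nMYC\t5\t5\n")
        (tmp_path / "meta.tsv").write_text("sample\tgroup\ns1\tAA\ns2\tEA\n")

    def test_tsv_round_trip_into_profiles(self, tmp_path):
        self._tables(tmp_path)
        profiles = cohort_profiles(
            read_metadata(tmp_path / "meta.tsv"),
            mutations=read_mutations(tmp_path / "mut.tsv"),
            cnv=read_cnv(tmp_path / "cnv.tsv"),
            expression=read_expression(tmp_path / "expr.tsv"),
            cnv_kind="lrr",
        )
        p1 = profiles["s1"]
        assert p1.group == "AA"
        assert p1.mutations[0].gene == "TP53"
        assert p1.ploidy["MYC"] == 2  # 0.9 > 0.7
        assert p1.expression["TP53"] == 0.0 and p1.expression["MYC"] == 0.5

    def test_per_sample_independence_of_discrete_channels(self, tmp_path, small_net):
        """Another sample's mutations never leak into this sample's model."""
        self._tables(tmp_path)
        meta = read_metadata(tmp_path / "meta.tsv")
        expr = read_expression(tmp_path / "expr.tsv")
        mut = read_mutations(tmp_path / "mut.tsv")
        base = cohort_profiles(meta, mutations=mut, expression=expr)
        extra = pd.concat(
            [mut, pd.DataFrame([{"sample": "s2", "gene": "MYC", "effect": "activating"}])]
        )
        withx = cohort_profiles(meta, mutations=extra, expression=expr)
        m1 = build_personalized_model(base["s1"], small_net)
        m2 = build_personalized_model(withx["s1"], small_net)
        assert m1.forcings == m2.forcings and m1.rates.up == m2.rates.up

    def test_effect_vocabulary_enforced(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("sample\tgene\teffect\ns1\tTP53\tweird\n")
        with pytest.raises(ValueError, match="unknown mutation effects"):
            read_mutations(tmp_path / "bad.tsv")
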