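import numpy as np
import pandas as pd
import pytest
from scipy import stats

from boolomics.logic import (
    downstream_nodes,
    influence_graph,
    semantic_regulators,
    write_rules,
)
from boolomics.methylation import select_representative_probe, spearman
from boolomics.personalize import (
    cohort_profiles,
    read_cnv,
    read_expression,
    read_metadata,
    read_mutations,
)
from boolomics.synthetic import (
    TOY_NON_GENE_NODES,
    CohortSpec,
    PlantedEffect,
    generate_random_network,
    simulate_cohort,
    simulate_methylation_coupling,
    toy_ar_network,
    toy_cohort_spec,
    write_cohort,
)


class TestToyFixture:
    def test_fixture_is_frozen(self):
        n1, n2 = toy_ar_network(), toy_ar_network()
        assert write_rules(n1) == write_rules(n2)
        assert len(n1.nodes) == 11
        assert len(influence_graph(n1)) == len(influence_graph(n2))

    def test_required_nodes_present_with_pathways(self, toy_net):
        for node in ("AR", "AR_ERG", "IDH1", "SMAD", "ZBTB17"):
            assert node in toy_net.nodes
        assert toy_net.pathway_of("SMAD") == "TGF_beta"
        assert toy_net.pathway_of("E2F") == "Cell_cycle"

    def test_ar_drives_fusion_and_represses_tgf_branch(self, toy_net):
        edges = influence_graph(toy_net)
        assert ("AR", "AR_ERG", 1) in edges
        assert ("AR", "ZBTB17", 1) in edges
        assert ("AR", "SMAD", -1) in edges
        assert ("AR", "IDH1", -1) in edges

    def test_all_nodes_reachable_from_inputs(self, toy_net):
        inputs = ("Androgen", "GrowthFactor", "TGFB")
        assert downstream_nodes(toy_net, inputs) == frozenset(toy_net.nodes)


class TestRandomNetworks:
    def test_seed_reproducibility(self):
        n1 = generate_random_network(6, 3, seed=4)
        n2 = generate_random_network(6, 3, seed=4)
        assert write_rules(n1) == write_rules(n2)

    def test_single_node_self_regulates(self):
        net = generate_random_network(1, 1, seed=0)
        assert net.rule(net.nodes[0]).regulators == (net.nodes[0],)

    @pytest.mark.parametrize("seed", range(5))
    def test_no_vacuous_literals(self, seed):
        net = generate_random_network(8, 3, seed=seed)
        for rule in net.rules:
            assert semantic_regulators(rule) == set(rule.regulators)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            generate_random_network(0, 1, seed=0)
        with pytest.raises(ValueError):
            generate_random_network(3, 4, seed=0)


class TestCohortGeneration:
    def test_same_seed_gives_identical_tables(self):
        _, t1 = simulate_cohort(toy_cohort_spec(3))
        _, t2 = simulate_cohort(toy_cohort_spec(3))
        pd.testing.assert_frame_equal(t1.expression, t2.expression)
        pd.testing.assert_frame_equal(t1.cnv_lrr, t2.cnv_lrr)
        pd.testing.assert_frame_equal(t1.mutations, t2.mutations)

    def test_different_seed_changes_data_not_schema(self):
        _, t1 = simulate_cohort(toy_cohort_spec(3))
        _, t2 = simulate_cohort(toy_cohort_spec(4))
        assert list(t1.expression.index) == list(t2.expression.index)
        assert list(t1.expression.columns) == list(t2.expression.columns)
        assert not t1.expression.equals(t2.expression)

    def test_non_gene_nodes_absent_from_omics(self):
        _, tables = simulate_cohort(toy_cohort_spec(0))
        for node in TOY_NON_GENE_NODES:
            assert node not in tables.expression.index
            assert node not in tables.cnv_lrr.index

    def test_planted_target_must_be_a_gene(self, toy_net):
        with pytest.raises(ValueError, match="gene universe"):
            CohortSpec(
                network=toy_net,
                planted_effects=(PlantedEffect("NOSUCH", "expression_shift", 1.0),),
            )
        with pytest.raises(ValueError, match="gene universe"):
            toy_cohort_spec(
                0, planted_effects=(PlantedEffect("SMAD", "expression_shift", 1.0),)
            )

    def test_written_cohort_round_trips_into_profiles(self, tmp_path):
        spec = toy_cohort_spec(1, n_per_group=4)
        paths = write_cohort(spec, tmp_path)
        profiles = cohort_profiles(
            read_metadata(paths["metadata"]),
            mutations=read_mutations(paths["mutations"]),
            cnv=read_cnv(paths["cnv_lrr"]),
            expression=read_expression(paths["expression"]),
            cnv_kind="lrr",
        )
        assert len(profiles) == 8
        sample = next(iter(profiles.values()))
        assert all(0.0 <= x <= 1.0 for x in sample.expression.values())
        assert paths["rules"].read_text() == write_rules(spec.network)

    def test_planted_expression_shift_moves_group_means(self):
        spec = toy_cohort_spec(
            5, planted_effects=(PlantedEffect("TGFB", "expression_shift", 4.0, group="AA"),)
        )
        _, tables = simulate_cohort(spec)
        log2 = np.log2(tables.expression.loc["TGFB"])
        aa = log2[[c for c in log2.index if c.startswith("AA")]]
        ea = log2[[c for c in log2.index if c.startswith("EA")]]
        assert aa.mean() - ea.mean() > 2.0

    def test_planted_cnv_shift_yields_extreme_ploidy(self):
        spec = toy_cohort_spec(
            6, planted_effects=(PlantedEffect("AR", "cnv", 1.5, group="AA"),)
        )
        _, tables = simulate_cohort(spec)
        aa_cols = [c for c in tables.cnv_lrr.columns if c.startswith("AA")]
        ea_cols = [c for c in tables.cnv_lrr.columns if c.startswith("EA")]
        assert (tables.cnv_lrr.loc["AR", aa_cols] > 0.7).mean() > 0.5
        assert (tables.cnv_lrr.loc["AR", ea_cols] > 0.7).mean() < 0.2

    def test_groups_exchangeable_without_planted_effects(self):
        """Pooled over replicates, the two groups' log-expression agrees (KS)."""
        aa, ea = [], []
        for seed in range(10):
            _, tables = simulate_cohort(toy_cohort_spec(400 + seed))
            log2 = np.log2(tables.expression.loc["AR"])
            aa.extend(log2[[c for c in log2.index if c.startswith("AA")]])
            ea.extend(log2[[c for c in log2.index if c.startswith("EA")]])
        assert stats.ks_2samp(aa, ea).pvalue > 0.01


class TestMethylationCoupling:
    def _spec(self, magnitude, seed=0, n=10):
        return CohortSpec(
            network=toy_ar_network(),
            n_per_group=n,
            seed=seed,
            non_gene_nodes=TOY_NON_GENE_NODES,
            planted_effects=(
                PlantedEffect("IDH1", "methylation_coupling", magnitude),
            ),
        )

    def _stratum_rho(self, meth, gene, tissue="tumor", group="AA"):
        dmr = next(d for d in meth.dmrs if d.leading_gene == gene)
        probe = select_representative_probe(dmr, meth.beta)
        meta = meth.metadata.set_index("sample")
        ids = meta.index[(meta.tissue == tissue) & (meta.group == group)]
        return spearman(
            meth.beta.loc[probe, ids].to_numpy(),
            meth.expression.loc[gene, ids].to_numpy(),
        )

    def test_noise_free_coupling_is_perfectly_inverse(self):
        meth = simulate_methylation_coupling(self._spec(1.0))
        rho, _ = self._stratum_rho(meth, "IDH1")
        assert rho == pytest.approx(-1.0)

    def test_zero_magnitude_is_centred_at_zero(self):
        rhos = [
            self._stratum_rho(simulate_methylation_coupling(self._spec(0.0, seed=s)), "IDH1")[0]
            for s in range(10)
        ]
        assert abs(np.mean(rhos)) < 0.2

    def test_uncoupled_filler_genes_near_zero(self):
        meth = simulate_methylation_coupling(self._spec(1.0, n=15))
        rho, _ = self._stratum_rho(meth, "GENE01")
        assert abs(rho) < 0.6

    def test_representative_probe_has_largest_range_by_construction(self):
        meth = simulate_methylation_coupling(self._spec(0.6))
        for dmr in meth.dmrs:
            sub = meth.beta.loc[list(dmr.probes)]
            ranges = sub.max(axis=1) - sub.min(axis=1)
            assert ranges.idxmax() == select_representative_probe(dmr, meth.beta)

    def test_beta_values_strictly_inside_unit_interval(self):
        meth = simulate_methylation_coupling(self._spec(0.6, seed=2))
        vals = meth.beta.to_numpy()
        assert np.all((vals > 0.0) & (vals < 1.0))

    def test_out_of_range_magnitude_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            self._spec(1.2)

    def test_requires_a_coupling_effect(self):
        with pytest.raises(ValueError, match="methylation_coupling"):
            simulate_methylation_coupling(toy_cohort_spec(0))

    def test_seed_reproducibility(self):
        m1 = simulate_methylation_coupling(self._spec(0.6, seed=5))
        m2 = simulate_methylation_coupling(self._spec(0.6, seed=5))
        pd.testing.assert_frame_equal(m1.beta, m2.beta)
        assert m1.dmrs == m2.dmrs


def test_cohort_spec_from_yaml(tmp_path):
    yaml_text = """\
n_per_group: 4
seed: 9
noise_sd: 0.4
group_labels: [AA, EA]
non_gene_nodes: [Androgen, GrowthFactor, SMAD, Proliferation]
planted_effects:
  - {target: TGFB, channel: expression_shift, magnitude: 4.0, group: AA}
"""
    path = tmp_path / "spec.yaml"
    path.write_text(yaml_text)
    spec = CohortSpec.from_yaml(path)  # defaults to the toy network
    assert spec.n_per_group == 4 and spec.seed == 9
    assert spec.planted_effects[0].target == "TGFB"
    assert spec.network.nodes == toy_ar_network().nodes
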