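"""Relevance statistic, permutation null and Z-score contracts."""

import numpy as np
import pytest

from netpharm import (
    DegenerateNullError,
    InputDataError,
    NullDistribution,
    RWRConfig,
    ScoreVector,
    assess_seed_sets,
    build_transition,
    relevance,
    restrict_seeds,
    run_rwr,
    sample_null,
    seed_distribution,
    z_score,
)


def _vec(values, nodes=None):
    values = np.asarray(values, dtype=float)
    nodes = tuple(nodes or (f"n{i}" for i in range(len(values))))
    return ScoreVector(nodes, values / values.sum())


class TestRelevance:
    def test_self_correlation_is_one(self):
        v = _vec([0.5, 0.3, 0.1, 0.1])
        assert relevance(v, v) == pytest.approx(1.0)

    def test_affine_reversal_is_minus_one(self):
        x = np.array([0.5, 0.3, 0.1, 0.1])
        y = (x.max() + x.min()) - x
        assert relevance(_vec(x), _vec(y)) == pytest.approx(-1.0)

    def test_constant_field_is_an_error(self):
        flat = _vec([0.25] * 4)
        v = _vec([0.5, 0.3, 0.1, 0.1])
        with pytest.raises(InputDataError, match="constant"):
            relevance(flat, v)

    def test_mismatched_node_orders_rejected(self):
        a = _vec([0.6, 0.4], nodes=("x", "y"))
        b = _vec([0.6, 0.4], nodes=("y", "x"))
        with pytest.raises(InputDataError):
            relevance(a, b)

    def test_exclude_indices_change_the_support(self):
        x = _vec([0.6, 0.2, 0.1, 0.1])
        y = _vec([0.1, 0.2, 0.3, 0.4])
        full = relevance(x, y)
        partial = relevance(x, y, exclude_indices=[0])
        expected = np.corrcoef([0.2, 0.1, 0.1], [0.2, 0.3, 0.4])[0, 1]
        assert partial == pytest.approx(expected)
        assert partial != pytest.approx(full)


class TestZScore:
    def test_centered_relevance_gives_zero(self):
        null = NullDistribution([0.1] * 3 + [0.3], 0.1, 0.2, 4, 0, 5)
        assert z_score(0.1, null) == 0.0

    def test_forced_arithmetic(self):
        null = NullDistribution([], 0.1, 0.2, 0, 0, 5)
        assert z_score(0.5, null) == pytest.approx(2.0)

    def test_absolute_deviation(self):
        null = NullDistribution([], 0.1, 0.2, 0, 0, 5)
        assert z_score(-0.3, null) == pytest.approx(2.0)

    def test_degenerate_null_raises(self):
        null = NullDistribution([0.2, 0.2], 0.2, 0.0, 2, 0, 5)
        with pytest.raises(DegenerateNullError, match="degenerate"):
            z_score(0.5, null)


class TestSampleNull:
    def _disease_field(self, scenario):
        net = scenario.network
        w = build_transition(net)
        seeds = restrict_seeds(scenario.disease_seeds, net, "disease")
        return net, w, run_rwr(w, seed_distribution(seeds, net), RWRConfig())

    def test_exact_repetition_count_and_moments(self, small_scenario):
        net, w, field = self._disease_field(small_scenario)
        null = sample_null(net, field, 20, n_perm=100, rng_seed=7, transition=w)
        assert null.n_perm == 100 and len(null.samples) == 100
        samples = np.array(null.samples)
        assert null.mu == pytest.approx(samples.mean())
        assert null.sigma == pytest.approx(samples.std(ddof=0))

    def test_seeded_determinism(self, small_scenario):
        net, w, field = self._disease_field(small_scenario)
        a = sample_null(net, field, 15, n_perm=30, rng_seed=11, transition=w)
        b = sample_null(net, field, 15, n_perm=30, rng_seed=11, transition=w)
        assert a.samples == b.samples

    def test_substreams_stable_when_n_perm_grows(self, small_scenario):
        # enlarging the permutation count must not reshuffle earlier draws
        net, w, field = self._disease_field(small_scenario)
        short = sample_null(net, field, 15, n_perm=20, rng_seed=11, transition=w)
        long = sample_null(net, field, 15, n_perm=40, rng_seed=11, transition=w)
        assert long.samples[:20] == short.samples

    def test_all_nodes_seeded_gives_zero_sigma(self, small_scenario):
        net, w, field = self._disease_field(small_scenario)
        null = sample_null(net, field, net.n_nodes, n_perm=5, rng_seed=3, transition=w)
        assert null.sigma == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(DegenerateNullError):
            z_score(0.5, null)

    def test_oversized_request_rejected(self, small_scenario):
        net, w, field = self._disease_field(small_scenario)
        with pytest.raises(InputDataError):
            sample_null(net, field, net.n_nodes + 1, n_perm=5, rng_seed=3, transition=w)


class TestAssessSeedSets:
    def test_identical_lists_give_relevance_one_and_maximal_z(self, small_scenario):
        net = small_scenario.network
        genes = small_scenario.disease_seeds
        report = assess_seed_sets(genes, genes, net, n_perm=50, rng_seed=5)
        assert report.relevance == pytest.approx(1.0)
        # relevance = 1 is the maximum, so no other drug list sharing this
        # null can exceed this Z
        other = assess_seed_sets(
            list(net.node_order[:30]), genes, net, n_perm=50, rng_seed=5
        )
        if other.overlap_drug == report.overlap_drug:
            assert other.z_score <= report.z_score

    def test_report_is_byte_identical_across_runs(self, small_scenario):
        net = small_scenario.network
        kw = dict(
            network=net, n_perm=40, rng_seed=9,
            drug_label="drug", disease_label="disease",
        )
        a = assess_seed_sets(small_scenario.drug_seeds, small_scenario.disease_seeds, **kw)
        b = assess_seed_sets(small_scenario.drug_seeds, small_scenario.disease_seeds, **kw)
        assert a.to_json() == b.to_json()

    def test_planted_overlap_is_significant(self, small_scenario):
        report = assess_seed_sets(
            small_scenario.drug_seeds,
            small_scenario.disease_seeds,
            small_scenario.network,
            n_perm=100,
            rng_seed=21,
        )
        assert report.significant and report.z_score > 3

    def test_stage_name_in_error_message(self, small_scenario):
        with pytest.raises(InputDataError, match="restrict_seeds"):
            assess_seed_sets(
                ["not-a-node"],
                small_scenario.disease_seeds,
                small_scenario.network,
            )

    def test_report_fields_are_consistent(self, small_scenario):
        report = assess_seed_sets(
            small_scenario.drug_seeds,
            small_scenario.disease_seeds,
            small_scenario.network,
            n_perm=30,
            rng_seed=2,
        )
        assert report.z_score == pytest.approx(
            abs(report.relevance - report.null.mu) / report.null.sigma
        )
        assert report.significant == (report.z_score > 3)
        assert report.null.n_random_genes == report.overlap_drug
        assert -1.0 <= report.relevance <= 1.0

    def test_table_export_has_headline_columns(self, small_scenario, tmp_path):
        report = assess_seed_sets(
            small_scenario.drug_seeds,
            small_scenario.disease_seeds,
            small_scenario.network,
            n_perm=30,
            rng_seed=2,
        )
        out = tmp_path / "report.tsv"
        report.write_table(out)
        header, row = out.read_text().splitlines()
        assert header.split("\t") == ["Drug", "Overlap", "Relevance", "Z-score", "Significant"]
        assert int(row.split("\t")[1]) == report.overlap_drug
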