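"""Generator invariants: atlases, mixtures, bin counts, cohorts, amplification."""

import numpy as np
import pandas as pd
import pytest

from labs_cfdna import (
    ParameterError,
    SimulationConfig,
    build_reference_atlas,
    simulate_amplification,
    simulate_bin_counts,
    simulate_cohort,
    simulate_sample_calls,
)
from labs_cfdna.cnv import bin_genome
from labs_cfdna.methylome import summarize_regions


class TestAtlas:
    def test_margin_enforced_everywhere(self):
        atlas = build_reference_atlas(2, 10, marker_fraction=1.0, margin=0.8, seed=0)
        assert (np.abs(atlas.meth_prob[:, 0] - atlas.meth_prob[:, 1]) >= 0.8).all()

    def test_seed_determinism(self):
        a = build_reference_atlas(4, 100, seed=9)
        b = build_reference_atlas(4, 100, seed=9)
        np.testing.assert_array_equal(a.meth_prob, b.meth_prob)
        pd.testing.assert_frame_equal(a.sites, b.sites)

    def test_reference_scale_shape(self):
        atlas = build_reference_atlas(5, 333, marker_fraction=0.5, margin=0.6, seed=1)
        assert atlas.to_frame().shape == (333, 5)

    def test_probabilities_in_unit_interval(self, small_atlas):
        assert (small_atlas.meth_prob >= 0).all() and (small_atlas.meth_prob <= 1).all()

    def test_non_marker_sites_share_baseline(self, small_atlas):
        non_marker = small_atlas.meth_prob[small_atlas.marker_type == ""]
        assert (np.ptp(non_marker, axis=1) == 0).all()

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            build_reference_atlas(1, 10)
        with pytest.raises(ParameterError):
            build_reference_atlas(2, 10, marker_fraction=0.0)


class TestSampleCalls:
    def test_degenerate_mixture_tracks_atlas_column(self):
        atlas = build_reference_atlas(2, 400, marker_fraction=1.0, margin=0.8, seed=2)
        calls = simulate_sample_calls(atlas, [1.0, 0.0], coverage_mean=50, seed=3)
        obs = calls.set_index("pos0")[["n_meth", "n_unmeth"]]
        merged = atlas.sites.assign(p=atlas.meth_prob[:, 0]).set_index("pos0").join(obs)
        merged = merged.dropna()
        prop = merged["n_meth"] / (merged["n_meth"] + merged["n_unmeth"])
        se = np.sqrt(merged["p"] * (1 - merged["p"]) / 50).clip(lower=1e-3)
        within = (np.abs(prop - merged["p"]) <= 4 * se).mean()
        assert within > 0.99

    def test_conversion_failure_floor(self):
        atlas = build_reference_atlas(2, 2000, seed=4)
        atlas.meth_prob[:] = 0.0
        calls = simulate_sample_calls(atlas, [0.5, 0.5], coverage_mean=30,
                                      conversion_failure=0.01, seed=5)
        total = calls["n_meth"].sum() + calls["n_unmeth"].sum()
        level = calls["n_meth"].sum() / total
        se = np.sqrt(0.01 * 0.99 / total)
        assert abs(level - 0.01) <= 3 * se

    def test_mean_coverage(self):
        atlas = build_reference_atlas(2, 1000, seed=6)
        calls = simulate_sample_calls(atlas, [0.5, 0.5], coverage_mean=20, seed=7)
        # uncovered sites are dropped from the table; add them back as zeros
        mean_cov = (calls["n_meth"].sum() + calls["n_unmeth"].sum()) / 1000
        assert 19 <= mean_cov <= 21

    def test_counts_consistent(self, small_atlas):
        calls = simulate_sample_calls(small_atlas, np.full(5, 0.2), coverage_mean=10, seed=8)
        assert (calls["n_meth"] >= 0).all() and (calls["n_unmeth"] >= 0).all()
        assert ((calls["n_meth"] + calls["n_unmeth"]) > 0).all()

    def test_linear_mixing_identifiability(self):
        """With zero error rates, expected marker methylation = atlas @ w."""
        atlas = build_reference_atlas(3, 300, marker_fraction=1.0, margin=0.8, seed=10)
        w = np.array([0.5, 0.3, 0.2])
        calls = simulate_sample_calls(atlas, w, coverage_mean=500, seed=11)
        expected = atlas.meth_prob @ w
        obs = calls.set_index("pos0")[["n_meth", "n_unmeth"]]
        merged = atlas.sites.assign(e=expected).set_index("pos0").join(obs).dropna()
        prop = merged["n_meth"] / (merged["n_meth"] + merged["n_unmeth"])
        assert (prop - merged["e"]).abs().mean() < 0.02

    def test_off_simplex_rejected(self, small_atlas):
        with pytest.raises(ParameterError):
            simulate_sample_calls(small_atlas, [0.9, 0.2, 0, 0, 0])


class TestBinCounts:
    def test_total_conserved_exactly(self):
        bins = bin_genome({"chr1": 10**6}, 100_000)
        bc = simulate_bin_counts(bins, total_reads=10**6, seed=0)
        assert bc["count"].sum() == 10**6

    def test_neutral_genome_flat(self):
        bins = bin_genome({"chr1": 10**7}, 100_000)
        bc = simulate_bin_counts(bins, tumor_fraction=0.0, total_reads=10**7, seed=1)
        ratio = np.log2(bc["count"] / bc["count"].mean())
        assert ratio.abs().max() < 0.05

    def test_planted_gain_expected_weight(self):
        # copy 4 at tumor fraction 0.5 over a small slice of the genome:
        # relative weight 1 + 0.5*(4/2-1) = 1.5
        bins = bin_genome({"chr1": 10**7}, 100_000)
        seg = ("chr1", 0, 200_000, 4.0)
        bc = simulate_bin_counts(bins, [seg], tumor_fraction=0.5, total_reads=10**7, seed=2)
        inside = bc["count"][:2].mean()
        outside = bc["count"][2:].mean()
        assert inside / outside == pytest.approx(1.5, rel=0.05)

    def test_empty_bins_rejected(self):
        with pytest.raises(ParameterError):
            simulate_bin_counts(bin_genome({"chr1": 0}, 100), total_reads=10)


def _tiny_config(**kw):
    base = dict(
        n_cases=3, n_controls=3,
        genome=[("chr1", 300_000), ("chr2", 200_000)],
        cpg_per_kb=1.0, coverage_mean=30.0, reads_per_sample=50_000,
        dmrs=[("chr1", 100_000, 150_000, 0.4)],
        cna_segments=[("chr1", 200_000, 300_000, 3.0)],
        n_noncpg_sites=50, seed=123,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestCohort:
    def test_file_counts_and_truth(self, tmp_path):
        cohort = simulate_cohort(_tiny_config(), out_dir=tmp_path)
        assert len(cohort.calls) == 6 and len(cohort.bins) == 6
        assert len(list(tmp_path.glob("*.cov.tsv"))) == 6
        assert len(list(tmp_path.glob("*.bins.tsv"))) == 6
        assert (tmp_path / "truth.json").exists()
        props = cohort.truth.proportions_frame()
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-9)
        assert (props.to_numpy() >= 0).all()

    def test_byte_identical_for_same_seed(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(_tiny_config(), out_dir=d1)
        simulate_cohort(_tiny_config(), out_dir=d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()

    def test_planted_dmr_signal_scales_with_tumor_fraction(self):
        cfg = _tiny_config(n_cases=8, n_controls=8, coverage_mean=60.0,
                           tumor_fraction_range=(0.3, 0.3), marker_fraction=0.01)
        cohort = simulate_cohort(cfg)
        region = pd.DataFrame([("chr1", 100_000, 150_000, "dmr", ".")],
                              columns=["chrom", "start0", "end0", "name", "strand"])
        def region_level(calls):
            s = summarize_regions(calls[calls["context"] == "CpG"], region)
            return s["level"].iloc[0]
        case_levels = [region_level(cohort.calls[s["name"]])
                       for s in cohort.truth.samples if s["group"] == "case"]
        ctrl_levels = [region_level(cohort.calls[s["name"]])
                       for s in cohort.truth.samples if s["group"] == "control"]
        observed = np.mean(case_levels) - np.mean(ctrl_levels)
        # delta * tumor_fraction, attenuated where baseline clips near 1
        assert observed == pytest.approx(0.4 * 0.3, abs=0.06)

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            _tiny_config(tumor_fraction_range=(0.5, 0.2))
        with pytest.raises(ParameterError):
            _tiny_config(cna_segments=[("chr1", 0, 10, -1.0)])


class TestAmplification:
    def test_single_molecule_all_duplicates(self):
        ids = simulate_amplification(1, 10, seed=0)
        assert np.unique(ids).size == 1

    def test_mean_copies_below_one_rejected(self):
        with pytest.raises(ParameterError):
            simulate_amplification(10, 10, mean_copies=0.5)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ParameterError):
            simulate_amplification(10, 10, mode="pcr")

    def test_exponential_duplicates_more_than_linear(self):
        """Heavier-tailed copy distributions raise collision probability."""
        from labs_cfdna import duplication_rate
        lin, exp = [], []
        for s in range(30):
            lin.append(duplication_rate(simulate_amplification(
                2000, 4000, mode="linear", mean_copies=5, seed=s)))
            exp.append(duplication_rate(simulate_amplification(
                2000, 4000, mode="exponential", mean_copies=5, jitter=1.5, seed=s)))
        assert np.mean(exp) > np.mean(lin)
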