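"""Synthetic cohort generator: abundance model, rearrangement drawing,
sample/pair/cohort simulation, determinism and parameter recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcrskin import clonality, common_clones, diversity_table, simulate_cohort
from tcrskin.errors import ParameterError
from tcrskin.simulate import (
    CDR3_NT_RANGE,
    DEFAULT_SEGMENTS,
    GeneSegmentUsage,
    GroupSpec,
    _batch_cdr3,
    _entropy_deficit_bits,
    generate_rearrangement,
    sample_clone_frequencies,
    shape_for_clonality,
    simulate_paired,
    simulate_sample,
    study_config,
)
from tcrskin.types import Chain, SampleMetadata, TissueGroup

from conftest import small_config


class TestCloneFrequencies:
    def test_single_clone_is_forced_to_one(self, rng):
        assert sample_clone_frequencies(1, 2.0, rng).tolist() == [1.0]

    def test_large_shape_approaches_uniformity(self):
        p = sample_clone_frequencies(1000, 50.0, np.random.default_rng(7))
        assert clonality(p) < 0.05

    def test_deterministic_given_seed(self):
        a = sample_clone_frequencies(100, 2.0, np.random.default_rng(3))
        b = sample_clone_frequencies(100, 2.0, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_nonpositive_shape_rejected(self, rng):
        with pytest.raises(ParameterError):
            sample_clone_frequencies(10, 0.0, rng)

    def test_normalized_and_positive(self, rng):
        p = sample_clone_frequencies(500, 1.5, rng)
        assert (p > 0).all() and p.sum() == pytest.approx(1.0)


class TestShapeCalibration:
    def test_deficit_formula_solved_exactly(self):
        for n, c in [(400, 0.08), (1570, 0.08), (100, 0.2)]:
            a = shape_for_clonality(n, c)
            assert _entropy_deficit_bits(a) == pytest.approx(c * math.log2(n), rel=1e-9)

    def test_realized_clonality_near_target(self):
        # large-n check of the asymptotic calibration
        rng = np.random.default_rng(11)
        a = shape_for_clonality(20_000, 0.1)
        cs = [clonality(sample_clone_frequencies(20_000, a, rng)) for _ in range(5)]
        assert np.mean(cs) == pytest.approx(0.1, abs=0.03)


class TestRearrangements:
    def test_single_v_label_always_used(self, rng):
        segs = GeneSegmentUsage(v={"TRGV9": 1.0}, j={"TRGJ1": 2.0, "TRGJ2": 1.0})
        for _ in range(20):
            assert generate_rearrangement(segs, rng)["v_gene"] == "TRGV9"

    def test_cdr3_in_frame_stop_free_and_translated(self, rng):
        nt, aa = _batch_cdr3(500, rng)
        lo, hi = CDR3_NT_RANGE
        for s_nt, s_aa in zip(nt, aa):
            assert len(s_nt) % 3 == 0 and lo <= len(s_nt) <= hi
            assert len(s_aa) == len(s_nt) // 3
            assert "*" not in s_aa

    def test_weighted_usage_within_binomial_error(self):
        from tcrskin.simulate import _sample_genes

        draws = _sample_genes({"A": 0.9, "B": 0.1}, 10_000, np.random.default_rng(2))
        p_hat = float(np.mean(draws == "A"))
        assert abs(p_hat - 0.9) < 3 * math.sqrt(0.9 * 0.1 / 10_000)


class TestSimulateSample:
    def test_depth_one_gives_single_observed_clone(self):
        cfg = small_config()
        spec = GroupSpec(group="normal", n_samples=1, richness_mean=50,
                         richness_dispersion=0.0, depth=50)
        rep = simulate_sample(
            spec, cfg, np.random.default_rng(0),
            metadata=SampleMetadata("s", "p", "normal", "TRG"),
        )
        # depth=1 via _observe directly: one multinomial trial
        from tcrskin.simulate import _observe, _unique_skeletons

        rng = np.random.default_rng(1)
        skel = _unique_skeletons(10, cfg.gene_segments, rng)
        f = sample_clone_frequencies(10, 5.0, rng)
        one = _observe(skel, f, 1, rep.metadata, rng)
        assert one.n_unique == 1 and one.total_count == 1

    def test_same_seed_identical_repertoire(self):
        cfg = small_config()
        spec = cfg.spec("lesional")
        md = SampleMetadata("s", "p", "lesional", "TRG")
        a = simulate_sample(spec, cfg, np.random.default_rng(5), metadata=md)
        b = simulate_sample(spec, cfg, np.random.default_rng(5), metadata=md)
        pd.testing.assert_frame_equal(a.clones, b.clones)

    def test_depth_below_richness_rejected(self):
        with pytest.raises(ParameterError):
            GroupSpec(group="normal", n_samples=1, richness_mean=100, depth=50)

    def test_richness_recovered_at_ample_depth(self):
        """Multinomial-coverage oracle: near-uniform weights at depth
        10x richness recover the configured richness within 20%."""
        cfg = small_config(freq_shape=50.0)
        spec = GroupSpec(group="normal", n_samples=1, richness_mean=100,
                         richness_dispersion=0.0, depth=1000)
        md = SampleMetadata("s", "p", "normal", "TRG")
        observed = [
            simulate_sample(spec, cfg, np.random.default_rng(seed), metadata=md).n_unique
            for seed in range(50)
        ]
        assert abs(np.mean(observed) - 100) / 100 < 0.20


class TestSimulatePaired:
    def _specs(self, richness=200):
        nl = GroupSpec(group="non_lesional", n_samples=1, richness_mean=richness,
                       richness_dispersion=0.0, depth=100 * richness)
        ls = GroupSpec(group="lesional", n_samples=1, richness_mean=richness,
                       richness_dispersion=0.0, depth=100 * richness)
        return nl, ls

    def test_zero_sharing_rate_gives_disjoint_keys(self):
        nl_spec, ls_spec = self._specs()
        cfg = small_config(paired_sharing_rate=0.0)
        nl, ls = simulate_paired("p1", nl_spec, ls_spec, cfg, np.random.default_rng(2))
        assert not (nl.key_set() & ls.key_set())

    def test_full_sharing_equal_richness_gives_jaccard_one(self):
        from tcrskin import overlap_score

        nl_spec, ls_spec = self._specs(100)
        cfg = small_config(paired_sharing_rate=1.0)
        nl, ls = simulate_paired("p1", nl_spec, ls_spec, cfg, np.random.default_rng(3))
        rec = overlap_score(nl, ls, key_mode="nt_vj")
        assert rec.score == 1.0

    def test_excessive_sharing_demand_rejected(self):
        nl = GroupSpec(group="non_lesional", n_samples=1, richness_mean=10,
                       richness_dispersion=0.0, depth=200)
        ls = GroupSpec(group="lesional", n_samples=1, richness_mean=100,
                       richness_dispersion=0.0, depth=2000)
        cfg = small_config(paired_sharing_rate=0.5)
        with pytest.raises(ParameterError, match="sharing rate"):
            simulate_paired("p1", nl, ls, cfg, np.random.default_rng(0))

    def test_latent_rank_correlation_tracks_config(self):
        """Rank-correlation oracle on the generator's latent frequencies."""
        nl_spec, ls_spec = self._specs(200)
        cfg = small_config(paired_sharing_rate=0.5, paired_freq_correlation=0.9)
        rhos = []
        for seed in range(20):
            _, _, latent = simulate_paired(
                "p1", nl_spec, ls_spec, cfg, np.random.default_rng(seed),
                return_latent=True,
            )
            rhos.append(
                stats.spearmanr(latent["shared_freq_nl"], latent["shared_freq_ls"]).statistic
            )
        assert np.mean(rhos) > 0.6

    def test_same_patient_id_on_both_outputs(self):
        nl_spec, ls_spec = self._specs(50)
        cfg = small_config()
        nl, ls = simulate_paired("pat7", nl_spec, ls_spec, cfg, np.random.default_rng(1))
        assert nl.metadata.patient_id == ls.metadata.patient_id == "pat7"
        assert nl.metadata.group is TissueGroup.NON_LESIONAL
        assert ls.metadata.group is TissueGroup.LESIONAL


class TestSimulateCohort:
    def test_study_design_counts(self):
        cohort = simulate_cohort(small_config(n_public_clones=3, seed=4))
        assert len(cohort.repertoires) == 20
        assert len(cohort.manifest) == 20
        groups = cohort.manifest["group"].value_counts()
        assert groups["normal"] == 7
        assert groups["non_lesional"] == 5
        assert groups["lesional"] == 8
        # 5 paired patients share ids between NL and LS
        nl_pat = set(cohort.manifest.query("group == 'non_lesional'")["patient_id"])
        ls_pat = set(cohort.manifest.query("group == 'lesional'")["patient_id"])
        assert len(nl_pat & ls_pat) == 5

    def test_public_clones_recovered_in_lesional_intersection(self):
        cohort = simulate_cohort(small_config(n_public_clones=3, seed=8))
        report = common_clones(cohort.by_group("lesional"), key_mode="aa_only")
        assert report.n_clones >= 3

    def test_public_clones_absent_from_normal_samples(self):
        for seed in range(5):
            cohort = simulate_cohort(small_config(n_public_clones=0, seed=seed))
            report = common_clones(cohort.by_group("normal"), key_mode="aa_only")
            assert report.n_clones == 0

    def test_bit_reproducible_given_seed(self):
        a = simulate_cohort(small_config(n_public_clones=2, seed=12))
        b = simulate_cohort(small_config(n_public_clones=2, seed=12))
        for ra, rb in zip(a.repertoires, b.repertoires):
            pd.testing.assert_frame_equal(ra.clones, rb.clones)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)

    def test_identical_shape_keeps_group_clonality_close(self):
        """With one shared freq_shape, mean clonality differs across
        groups by < 0.05 even at a 3-fold richness gap (50 seeds)."""
        diffs = []
        for seed in range(50):
            cfg = small_config(
                richness=(80, 110, 310), freq_shape=2.0, dispersion=0.25, seed=seed
            )
            div = diversity_table(simulate_cohort(cfg).repertoires)
            means = div.groupby("group")["clonality"].mean()
            diffs.append(means.max() - means.min())
        assert np.mean(diffs) < 0.05

    def test_study_config_trb_defaults(self):
        cfg = study_config("TRB", seed=0)
        assert cfg.chain is Chain.TRB
        assert cfg.n_public_clones == 0
        assert cfg.spec("lesional").richness_mean == 10900
        assert cfg.gene_segments is DEFAULT_SEGMENTS[Chain.TRB]
        # calibrated shapes fall with richness so clonality stays level
        shapes = {g.group.value: g.freq_shape for g in cfg.groups}
        assert shapes["lesional"] < shapes["normal"]
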