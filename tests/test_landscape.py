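import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

from memtop import landscape as ls
from memtop import synthetic_data as sd
from memtop.fragment_match import FragmentMatch, match_fragments
from memtop.masses_ions import TheoreticalFragment, fragment_ladder, masked_sites
from memtop.synthetic_data import MS2Config, SimConfig


def make_match(site, ion="b", z=1, raw=10.0, length=None, mass=1000.0):
    frag = TheoreticalFragment(ion, site, length or site, mass)
    return FragmentMatch(frag, z, 500.0, 0.0, raw)


class TestNormalizeByCharge:
    def test_divide(self):
        (m,) = ls.normalize_by_charge([make_match(1, z=3, raw=600.0)])
        assert m.normalized_intensity == pytest.approx(200.0)

    def test_unit_charge_unchanged(self):
        (m,) = ls.normalize_by_charge([make_match(1, z=1, raw=42.0)])
        assert m.normalized_intensity == pytest.approx(42.0)

    def test_equal_ion_counts(self):
        a, b = ls.normalize_by_charge(
            [make_match(1, z=3, raw=300.0), make_match(2, z=1, raw=100.0)]
        )
        assert a.normalized_intensity == pytest.approx(b.normalized_intensity)

    def test_alternative_modes(self):
        (m,) = ls.normalize_by_charge([make_match(1, z=4, raw=8.0)], mode="multiply")
        assert m.normalized_intensity == pytest.approx(32.0)
        (m,) = ls.normalize_by_charge([make_match(1, z=4, raw=8.0)], mode="none")
        assert m.normalized_intensity == pytest.approx(8.0)
        with pytest.raises(ValueError):
            ls.normalize_by_charge([make_match(1)], mode="log")


class TestSiteProfile:
    def test_single_match_scales_to_100(self):
        matches = ls.normalize_by_charge([make_match(5, raw=7.0)])
        prof = ls.site_profile(matches, 20)
        assert prof.abundance[4] == pytest.approx(100.0)
        assert prof.abundance.sum() == pytest.approx(100.0)

    def test_ratio_preserving_rescale(self):
        """Summed normalized 40 and 20 report as 100 and 50."""
        matches = ls.normalize_by_charge(
            [make_match(3, raw=40.0, z=1), make_match(7, raw=20.0, z=1)]
        )
        prof = ls.site_profile(matches, 20)
        assert prof.abundance[2] == pytest.approx(100.0)
        assert prof.abundance[6] == pytest.approx(50.0)

    def test_weighted_avg_charge(self):
        matches = ls.normalize_by_charge(
            [make_match(4, z=3, raw=30.0), make_match(4, z=5, raw=50.0)]
        )  # normalized intensities both 10
        prof = ls.site_profile(matches, 20)
        assert prof.weighted_avg_charge[3] == pytest.approx(4.0)
        assert prof.n_charge_states[3] == 2

    def test_no_matches_all_zero(self):
        prof = ls.site_profile([], 10)
        assert prof.abundance.sum() == 0.0

    def test_requires_normalization(self):
        with pytest.raises(ValueError, match="normalize"):
            ls.site_profile([make_match(1)], 10)

    def test_rescale_preserves_ratios(self):
        matches = ls.normalize_by_charge(
            [make_match(i, raw=float(i * 3), z=1) for i in range(1, 8)]
        )
        prof = ls.site_profile(matches, 20)
        raw = prof.raw_abundance[:7]
        scaled = prof.abundance[:7]
        np.testing.assert_allclose(scaled / scaled[0], raw / raw[0])


class TestCoverage:
    def test_full(self):
        matches = [make_match(i) for i in range(1, 10)]
        assert ls.coverage(matches, 10) == pytest.approx(100.0)

    def test_none(self):
        assert ls.coverage([], 10) == 0.0

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            ls.coverage([], 1)

    def test_simulated_distinct_sites(self, gpcr_spec, noiseless_cfg):
        peaks, truth = sd.simulate_ms2(gpcr_spec, 17, "IRMPD", noiseless_cfg, seed=1)
        matches = match_fragments(peaks, fragment_ladder(gpcr_spec), 16, 10.0)
        L = len(gpcr_spec)
        assert ls.coverage(matches, L) == pytest.approx(
            100.0 * len(truth.emitted_sites()) / (L - 1)
        )

    def test_monotone_in_matches(self):
        matches = [make_match(i) for i in (3, 8, 8, 15, 2)]
        vals = [ls.coverage(matches[:k], 30) for k in range(len(matches) + 1)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestSequenceTags:
    def test_run_of_four_sites(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        matches = [make_match(s) for s in (10, 11, 12, 13)]
        tags = ls.sequence_tags(matches, seq, min_len=3)
        assert len(tags) == 1
        tag = tags[0]
        assert (tag.start, tag.end) == (11, 13)
        assert tag.residues == seq[10:13]
        assert tag.sites == (10, 11, 12, 13)

    def test_isolated_sites_no_tags(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        matches = [make_match(s) for s in (2, 5, 9, 14)]
        assert ls.sequence_tags(matches, seq, min_len=3) == []

    def test_full_ladder_single_tag(self):
        seq = "ACDEFGHIKL"
        matches = [make_match(s) for s in range(1, len(seq))]
        tags = ls.sequence_tags(matches, seq, min_len=3)
        assert len(tags) == 1
        assert (tags[0].start, tags[0].end) == (2, len(seq) - 1)
        assert tags[0].residues == seq[1:-1]

    def test_min_len_one(self):
        seq = "ACDEFGHIKL"
        tags = ls.sequence_tags([make_match(4), make_match(5)], seq, min_len=1)
        assert len(tags) == 1
        assert tags[0].residues == seq[4:5]

    def test_tags_mostly_in_tm_helices(self, gpcr_spec, noiseless_cfg):
        cfg = dataclasses.replace(noiseless_cfg, ms2=MS2Config(n_fragments=400))
        peaks, _ = sd.simulate_ms2(gpcr_spec, 17, "IRMPD", cfg, seed=3)
        matches = match_fragments(peaks, fragment_ladder(gpcr_spec), 16, 10.0)
        tags = ls.sequence_tags(matches, gpcr_spec.sequence, min_len=3)
        assert tags
        in_tm = sum(
            1
            for t in tags
            if gpcr_spec.helix_of_residue((t.start + t.end) // 2) is not None
        )
        assert in_tm / len(tags) > 0.5


class TestPairHeatmap:
    def test_single_pair_cell(self):
        seq = "KAGAGL"
        matches = ls.normalize_by_charge(
            [make_match(2, raw=10.0), make_match(4, raw=5.0)]
        )  # both A|G sites
        H = ls.pair_heatmap(matches, seq)
        a, g = ls.AMINO_ACIDS.index("A"), ls.AMINO_ACIDS.index("G")
        assert H[a, g] == pytest.approx(15.0)
        assert H.sum() == pytest.approx(15.0)

    def test_total_conservation_with_profile(self, gpcr_spec, default_cfg):
        peaks, _ = sd.simulate_ms2(gpcr_spec, 17, "IRMPD", default_cfg, seed=6)
        matches = ls.normalize_by_charge(
            match_fragments(peaks, fragment_ladder(gpcr_spec), 16, 10.0)
        )
        prof = ls.site_profile(matches, len(gpcr_spec))
        H = ls.pair_heatmap(matches, gpcr_spec.sequence)
        assert H.sum() == pytest.approx(prof.raw_abundance.sum())

    def test_elevated_proline_weights_dominate_recovered_map(self):
        """pair_weights boosted 10x for X|P: the argmax column is P."""
        cfg_ms2 = MS2Config(
            pair_weights={"X|P": 10.0},
            helix_weight_scale=0.0,
            loop_basic_residue_penalty=1.0,
            min_propensity_floor=0.01,
            n_fragments=400,
        )
        p_col = ls.AMINO_ACIDS.index("P")
        hits = 0
        for seed in range(10):
            spec = sd.make_protein(4, 22, 12, 0, seed=seed, pro_freq=0.08)
            cfg = SimConfig(ms2=cfg_ms2).noiseless()
            peaks, _ = sd.simulate_ms2(spec, 12, "IRMPD", cfg, seed=seed)
            matches = ls.normalize_by_charge(
                match_fragments(peaks, fragment_ladder(spec), 11, 10.0)
            )
            H = ls.pair_heatmap(matches, spec.sequence)
            hits += int(np.argmax(H.sum(axis=0)) == p_col)
        assert hits >= 8


class TestTopologyEnrichment:
    def _uniform_profile(self, spec, value=1.0):
        L = len(spec)
        matches = ls.normalize_by_charge(
            [make_match(i, raw=value) for i in range(1, L)]
        )
        return ls.site_profile(matches, L)

    def test_all_tm_abundance(self, gpcr_spec):
        tm_sites = [
            s
            for seg in gpcr_spec.tm_segments()
            for s in range(seg.start, min(seg.end + 1, len(gpcr_spec)))
        ]
        matches = ls.normalize_by_charge([make_match(s) for s in tm_sites])
        prof = ls.site_profile(matches, len(gpcr_spec))
        enr = ls.topology_enrichment(prof, gpcr_spec, n_perm=200, seed=0)
        assert enr.tm_fraction == pytest.approx(1.0)
        assert enr.p_value <= 0.05

    def test_uniform_abundance_matches_tm_fraction(self, gpcr_spec):
        prof = self._uniform_profile(gpcr_spec)
        enr = ls.topology_enrichment(prof, gpcr_spec, n_perm=200, seed=0)
        tm_site_frac = enr.tm_fraction
        L = len(gpcr_spec)
        n_tm = sum(
            min(seg.end, L - 1) - seg.start + 1 for seg in gpcr_spec.tm_segments()
        )
        assert tm_site_frac == pytest.approx(n_tm / (L - 1), abs=1e-9)
        # constant vector: every circular shift ties the observed statistic
        assert enr.p_value == pytest.approx(1.0)

    def test_random_abundance_p_value_is_uniformish(self, gpcr_spec):
        rng = np.random.default_rng(0)
        L = len(gpcr_spec)
        ps = []
        for _ in range(40):
            matches = ls.normalize_by_charge(
                [make_match(i, raw=float(rng.exponential(1.0)) + 1e-6) for i in range(1, L)]
            )
            prof = ls.site_profile(matches, L)
            enr = ls.topology_enrichment(prof, gpcr_spec, n_perm=100, seed=int(rng.integers(1e6)))
            ps.append(enr.p_value)
        assert 0.25 < float(np.mean(ps)) < 0.75

    def test_degenerate_profile(self, gpcr_spec):
        prof = ls.site_profile([], len(gpcr_spec))
        enr = ls.topology_enrichment(prof, gpcr_spec, n_perm=100, seed=0)
        assert enr.degenerate and enr.p_value == 1.0

    def test_nperm_floor(self, gpcr_spec):
        prof = self._uniform_profile(gpcr_spec)
        with pytest.raises(ValueError):
            ls.topology_enrichment(prof, gpcr_spec, n_perm=10, seed=0)

    def test_power_under_strong_helix_weighting(self):
        """helix_weight_scale >> 1 gives p <= 0.05 in >= 90% of seeds."""
        spec = sd.make_protein(7, 24, 14, 0, seed=0, stability_profile=[1.0] * 7)
        cfg = SimConfig(
            ms2=MS2Config(helix_weight_scale=15.0, n_fragments=300)
        ).noiseless()
        ladder = fragment_ladder(spec)
        n_sig = 0
        n_seeds = 50
        for seed in range(n_seeds):
            peaks, _ = sd.simulate_ms2(spec, 17, "IRMPD", cfg, seed=seed)
            matches = ls.normalize_by_charge(match_fragments(peaks, ladder, 16, 10.0))
            prof = ls.site_profile(matches, len(spec))
            enr = ls.topology_enrichment(prof, spec, n_perm=199, seed=seed)
            n_sig += int(enr.p_value <= 0.05)
        assert n_sig >= int(0.9 * n_seeds)

    def test_per_helix_table_reports_skipped_helices(self):
        """Helices with zero stability weight contribute visibly less abundance."""
        stability = [1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0]
        spec = sd.make_protein(7, 24, 14, 0, seed=1, stability_profile=stability)
        cfg = SimConfig(
            ms2=MS2Config(helix_weight_scale=20.0, n_fragments=600)
        ).noiseless()
        peaks, _ = sd.simulate_ms2(spec, 17, "IRMPD", cfg, seed=2)
        matches = ls.normalize_by_charge(
            match_fragments(peaks, fragment_ladder(spec), 16, 10.0)
        )
        prof = ls.site_profile(matches, len(spec))
        enr = ls.topology_enrichment(prof, spec, n_perm=100, seed=0)
        strong = np.mean([enr.per_helix[h + 1] for h in range(7) if stability[h] == 1.0])
        weak = np.mean([enr.per_helix[h + 1] for h in range(7) if stability[h] == 0.0])
        assert strong > 3 * weak


class TestDisulfideExclusion:
    def test_masked_sites_have_zero_abundance(self, gpcr_spec, default_cfg):
        peaks, _ = sd.simulate_ms2(gpcr_spec, 17, "IRMPD", default_cfg, seed=7)
        matches = ls.normalize_by_charge(
            match_fragments(peaks, fragment_ladder(gpcr_spec), 16, 10.0)
        )
        prof = ls.site_profile(matches, len(gpcr_spec))
        for site in masked_sites(gpcr_spec.disulfides):
            assert prof.abundance[site - 1] == 0.0


class TestPropensityRecovery:
    def test_spearman_recovery(self, gpcr_spec):
        cfg = SimConfig(ms2=MS2Config(n_fragments=800)).noiseless()
        ladder = fragment_ladder(gpcr_spec)
        for seed in range(5):
            peaks, truth = sd.simulate_ms2(gpcr_spec, 17, "IRMPD", cfg, seed=seed)
            matches = ls.normalize_by_charge(match_fragments(peaks, ladder, 16, 10.0))
            prof = ls.site_profile(matches, len(gpcr_spec))
            rho = spearmanr(truth.propensity, prof.raw_abundance).statistic
            assert rho >= 0.8


class TestCompareModalities:
    def test_identical_inputs(self):
        matches = [make_match(5, mass=1000.0), make_match(9, mass=3000.0)]
        out = ls.compare_modalities(matches, matches, 20, labels=("a", "b"))
        assert out["a"] == out["b"]

    def test_hand_built_mean(self):
        matches = [make_match(5, mass=1000.0), make_match(9, mass=3000.0)]
        out = ls.compare_modalities(matches, matches, 20)
        assert out["IRMPD"]["mean_fragment_mass"] == pytest.approx(2000.0)

    def test_direction_irmpd_vs_hcd(self, gpcr_spec, default_cfg):
        ladder = fragment_ladder(gpcr_spec)
        pi, _ = sd.simulate_ms2(gpcr_spec, 17, "IRMPD", default_cfg, seed=13)
        ph, _ = sd.simulate_ms2(gpcr_spec, 17, "HCD", default_cfg, seed=13)
        mi = match_fragments(pi, ladder, 16, 10.0)
        mh = match_fragments(ph, ladder, 16, 10.0)
        out = ls.compare_modalities(mi, mh, len(gpcr_spec))
        assert out["IRMPD"]["mean_fragment_mass"] > out["HCD"]["mean_fragment_mass"]
        assert out["IRMPD"]["mean_fragment_charge"] > out["HCD"]["mean_fragment_charge"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ls.compare_modalities([], [make_match(1)], 10)
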