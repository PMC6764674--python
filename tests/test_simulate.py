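"""Synthetic-study generator: determinism, planted structure, calibration."""

import numpy as np
import pandas as pd
import pytest

import myocourse as mc
from myocourse.motifs import PWM
from myocourse.simulate import ClusterProfile


def informative_pwm(consensus, strength=0.91):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.full((4, len(consensus)), (1 - strength) / 3)
    for j, b in enumerate(consensus):
        mat[idx[b], j] = strength
    return PWM(id=f"pwm_{consensus}", tf_name="TF", matrix=mat)


class TestSpecValidation:
    def test_bad_values_rejected(self):
        with pytest.raises(ValueError):
            mc.SynthSpec(n_genes=0)
        with pytest.raises(ValueError):
            mc.SynthSpec(timepoints=(0, 2, 2, 8))
        with pytest.raises(ValueError):
            mc.SynthSpec(detection_dropout_rate=1.5)
        with pytest.raises(ValueError):
            mc.SynthSpec(probes_per_gene={1: 0.5, 2: 0.2})
        with pytest.raises(ValueError, match="unknown template"):
            mc.SynthSpec(cluster_profiles=(
                ClusterProfile("x", "sawtooth", {}),))


class TestTimecourse:
    def test_zero_noise_profiles_equal_templates(self):
        spec = mc.SynthSpec(n_genes=20, n_background_genes=0, noise_sd=0.0,
                            detection_dropout_rate=0.0,
                            cluster_profiles=mc.DEFAULT_PROFILES[:2],
                            probes_per_gene={1: 1.0}, seed=0)
        m, pg, truth = mc.simulate_timecourse(spec)
        assert m.flags.all().all()
        for probe in m.probes:
            gene = pg.gene_of(probe)
            expected = np.repeat(
                truth.cluster_centroids[truth.gene_cluster[gene]], 3
            )
            np.testing.assert_allclose(m.values.loc[probe], expected)

    def test_same_seed_identical_outputs(self):
        a = mc.simulate_timecourse(mc.SynthSpec(seed=42))
        b = mc.simulate_timecourse(mc.SynthSpec(seed=42))
        pd.testing.assert_frame_equal(a[0].values, b[0].values)
        pd.testing.assert_frame_equal(a[0].flags, b[0].flags)
        assert a[1].probe_to_gene == b[1].probe_to_gene
        assert a[2].gene_cluster == b[2].gene_cluster

    def test_different_seeds_differ(self):
        a = mc.simulate_timecourse(mc.SynthSpec(seed=1))
        b = mc.simulate_timecourse(mc.SynthSpec(seed=2))
        assert not a[0].values.equals(b[0].values)

    def test_replicate_structure_and_dropout_rate(self):
        spec = mc.SynthSpec(detection_dropout_rate=0.1, seed=3)
        m, _, _ = mc.simulate_timecourse(spec)
        days = m.samples["day"].value_counts()
        assert (days == 3).all() and len(days) == 8
        observed = 1.0 - m.flags.to_numpy().mean()
        n = m.flags.size
        assert abs(observed - 0.1) < 4 * np.sqrt(0.1 * 0.9 / n)

    def test_cluster_mean_profile_within_clt_bound(self):
        """Per-cluster mean of probe profiles stays within 3 standard
        errors of the template at every timepoint (checked over 20 seeds
        with a small allowance for the multiplicity of comparisons)."""
        bad = total = 0
        for seed in range(20):
            spec = mc.SynthSpec(n_genes=300, noise_sd=0.3, seed=seed,
                                probes_per_gene={1: 1.0},
                                n_background_genes=0)
            m, pg, truth = mc.simulate_timecourse(spec)
            day_means = m.mean_profile_by_day()
            genes = pd.Series({p: pg.gene_of(p) for p in day_means.index})
            for cname, members in truth.partition().items():
                probes = genes.index[genes.isin(members)]
                mean_profile = day_means.loc[probes].mean(axis=0)
                se = 0.3 / np.sqrt(len(probes) * 3)
                dev = np.abs(mean_profile.to_numpy()
                             - truth.cluster_centroids[cname])
                bad += int((dev > 3 * se).sum())
                total += len(dev)
        assert bad / total < 0.01      # 3-sigma exceedances are rare

    def test_multiprobe_genes_share_profile(self):
        spec = mc.SynthSpec(n_genes=60, n_background_genes=0,
                            probes_per_gene={3: 1.0}, noise_sd=0.2, seed=5)
        m, pg, truth = mc.simulate_timecourse(spec)
        assert m.values.shape[0] == 180
        probes_of = {}
        for p in m.probes:
            probes_of.setdefault(pg.gene_of(p), []).append(p)
        for gene, probes in probes_of.items():
            assert len(probes) == 3
            profiles = m.values.loc[probes].to_numpy()
            # same underlying curve, independent noise
            assert np.corrcoef(profiles[0], profiles[1])[0, 1] > 0.9
            assert not np.allclose(profiles[0], profiles[1])


class TestPromoters:
    def test_width_forces_sequence_length(self):
        spec = mc.SynthSpec(n_genes=12, n_background_genes=6, seed=0,
                            cluster_profiles=mc.DEFAULT_PROFILES[:2])
        _, _, truth = mc.simulate_timecourse(spec)
        proms = mc.simulate_promoters(spec, truth, [informative_pwm("ACGTACGT")],
                                      width=2000)
        assert all(len(p) == 4000 for p in proms.values())

    def test_equal_rates_give_equal_expected_hits(self):
        """fg rate == bg rate is the null construction: planted copy
        counts inside and outside the cluster agree in expectation."""
        pwm = informative_pwm("ACGTACGTGG")
        in_counts = out_counts = 0
        in_genes = out_genes = 0
        for seed in range(30):
            spec = mc.SynthSpec(
                n_genes=24, n_background_genes=24, seed=seed,
                cluster_profiles=mc.DEFAULT_PROFILES[:2],
                motif_planting={("somite", pwm.id): 0.25},
                motif_background_rate=0.25,
            )
            _, _, truth = mc.simulate_timecourse(spec)
            proms = mc.simulate_promoters(spec, truth, [pwm])
            for g, region in proms.items():
                n = region.sequence.count(pwm.consensus())
                if truth.gene_cluster[g] == "somite":
                    in_counts += n
                    in_genes += 1
                else:
                    out_counts += n
                    out_genes += 1
        rate_in = in_counts / in_genes
        rate_out = out_counts / out_genes
        assert rate_in == pytest.approx(rate_out, rel=0.25)

    def test_tenfold_planting_ratio(self):
        """fg rate 10x bg: Monte-Carlo mean copy count ratio ~= 10."""
        pwm = informative_pwm("ACGTACGTGG")
        fg = bg = 0
        fg_n = bg_n = 0
        for seed in range(50):
            spec = mc.SynthSpec(
                n_genes=16, n_background_genes=16, seed=seed,
                cluster_profiles=mc.DEFAULT_PROFILES[:2],
                motif_planting={("somite", pwm.id): 2.5},
                motif_background_rate=0.25,
            )
            _, _, truth = mc.simulate_timecourse(spec)
            proms = mc.simulate_promoters(spec, truth, [pwm])
            for g, region in proms.items():
                n = region.sequence.count(pwm.consensus())
                if truth.gene_cluster[g] == "somite":
                    fg += n
                    fg_n += 1
                else:
                    bg += n
                    bg_n += 1
        ratio = (fg / fg_n) / (bg / bg_n)
        assert ratio == pytest.approx(10.0, rel=0.2)

    def test_conservation_track_one_at_insertions(self):
        pwm = informative_pwm("ACGTACGTGG")
        spec = mc.SynthSpec(n_genes=8, n_background_genes=0, seed=1,
                            cluster_profiles=mc.DEFAULT_PROFILES[:2],
                            motif_planting={("somite", pwm.id): 2.0},
                            with_conservation=True)
        _, _, truth = mc.simulate_timecourse(spec)
        proms = mc.simulate_promoters(spec, truth, [pwm])
        somite = truth.partition()["somite"][0]
        region = proms[somite]
        pos = region.sequence.find(pwm.consensus())
        assert pos >= 0
        np.testing.assert_allclose(
            region.conservation[pos:pos + pwm.width], 1.0
        )

    def test_insertion_overflow_raises(self):
        pwm = informative_pwm("ACGTACGTGG")
        spec = mc.SynthSpec(n_genes=8, n_background_genes=0, seed=1,
                            cluster_profiles=mc.DEFAULT_PROFILES[:2],
                            motif_planting={("somite", pwm.id): 300.0})
        _, _, truth = mc.simulate_timecourse(spec)
        with pytest.raises(ValueError, match="overflow"):
            mc.simulate_promoters(spec, truth, [pwm], width=100)

    def test_unknown_planted_motif_rejected(self):
        spec = mc.SynthSpec(n_genes=8, n_background_genes=0, seed=1,
                            cluster_profiles=mc.DEFAULT_PROFILES[:2],
                            motif_planting={("somite", "nope"): 1.0})
        _, _, truth = mc.simulate_timecourse(spec)
        with pytest.raises(ValueError, match="not among"):
            mc.simulate_promoters(spec, truth, [informative_pwm("ACGTAC")])


class TestPartnerAndTargets:
    def test_noiseless_partner_equals_planted(self):
        spec = mc.SynthSpec(partner_correlation=1.0,
                            partner_unmapped_fraction=0.0,
                            partner_shared_fraction=1.0, seed=2)
        _, _, truth = mc.simulate_timecourse(spec)
        fc, omap, truth = mc.simulate_partner_dataset(spec, truth)
        for gene, sym in truth.partner_symbols.items():
            assert fc.mean[sym] == pytest.approx(truth.planted_log2fc[gene])

    def test_shared_fraction_respected(self):
        spec = mc.SynthSpec(n_genes=120, n_background_genes=80,
                            partner_shared_fraction=0.5, seed=2)
        _, _, truth = mc.simulate_timecourse(spec)
        fc, _, truth = mc.simulate_partner_dataset(spec, truth)
        assert len(fc.index) == 100

    def test_target_list_overlap_exact(self):
        spec = mc.SynthSpec(n_genes=120, n_background_genes=100, seed=6)
        _, _, truth = mc.simulate_timecourse(spec)
        design = {"A": {"myotome": 20, "somite": 5}, "B": {}}
        lists = mc.simulate_target_lists(truth, design, {"A": 60, "B": 25})
        by_name = {s.name: s for s in lists}
        part = truth.partition()
        assert len(by_name["A"].genes & set(part["myotome"])) == 20
        assert len(by_name["A"].genes & set(part["somite"])) == 5
        assert len(by_name["A"]) == 60
        # list B drawn entirely from background
        assert by_name["B"].genes <= set(truth.background_genes)

    def test_infeasible_design_rejected(self):
        spec = mc.SynthSpec(n_genes=12, n_background_genes=5, seed=0,
                            cluster_profiles=mc.DEFAULT_PROFILES[:2])
        _, _, truth = mc.simulate_timecourse(spec)
        with pytest.raises(ValueError, match="infeasible"):
            mc.simulate_target_lists(truth, {"A": {"somite": 100}})
        with pytest.raises(ValueError, match="infeasible"):
            mc.simulate_target_lists(truth, {"A": {"somite": 2}}, {"A": 50})

    def test_enrichment_pvalues_match_scipy_oracle(self, rng):
        """Designed overlaps scored downstream agree with the independent
        hypergeometric oracle."""
        from scipy import stats

        for seed in range(10):
            spec = mc.SynthSpec(n_genes=120, n_background_genes=100, seed=seed)
            _, _, truth = mc.simulate_timecourse(spec)
            k = int(rng.integers(0, 15))
            lists = mc.simulate_target_lists(truth, {"L": {"myotome": k}},
                                             {"L": 40})
            universe = set(truth.gene_cluster)
            rec = mc.list_representation(
                set(truth.partition()["myotome"]), lists[0], universe
            )
            ref = float(stats.hypergeom.sf(
                rec.overlap - 1, rec.universe_size, rec.list_size,
                rec.cluster_size,
            ))
            assert rec.p == pytest.approx(ref, rel=1e-9)
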