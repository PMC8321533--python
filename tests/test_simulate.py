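"""The synthetic-data generator: determinism, ploidy, moment recovery."""
import numpy as np
import pytest

import divscan as ds
from divscan import simulate as sim


def small_params(**kw):
    base = dict(chrom_lengths={"c1": 1_000_000}, t=600.0, ne=1000.0,
                mu=0.0, theta_anc=0.005, gene_flow=0.0, linked_selection=1.0,
                samples={"p1": (10, 5), "p2": (10, 5)})
    base.update(kw)
    return sim.SimParams(**base)


class TestParams:
    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            small_params(gene_flow=1.0)
        with pytest.raises(ValueError):
            small_params(linked_selection=0.0)

    def test_invalid_class_labels_rejected(self):
        p = small_params(window_classes=["weird"] * 50)
        with pytest.raises(ValueError, match="invalid window class"):
            p.classes()

    def test_truth_table_effective_times(self):
        cls = sim.block_classes(50, [(10, 5)], "barrier")
        p = small_params(window_classes=cls, gene_flow=0.4)
        truth = sim.simulate_frequencies(p, np.random.default_rng(0)).truth
        assert (truth.loc[truth["class"] == "barrier", "t_eff"] == 600).all()
        np.testing.assert_allclose(
            truth.loc[truth["class"] == "background", "t_eff"], 360.0)
        assert ((truth["F_exp"] >= 0) & (truth["F_exp"] < 1)).all()


class TestDeterminismAndPloidy:
    def test_fixed_seed_reproduces_everything(self):
        p = small_params()
        a = sim.simulate_frequencies(p, np.random.default_rng(9))
        b = sim.simulate_frequencies(p, np.random.default_rng(9))
        np.testing.assert_array_equal(a.pos, b.pos)
        np.testing.assert_array_equal(a.freqs, b.freqs)

    def test_haploids_never_heterozygous(self):
        p = small_params()
        rng = np.random.default_rng(1)
        sf = sim.simulate_frequencies(p, rng)
        table, geno = sim.sample_genotypes(sf, p, rng)
        hap_cols = [k for k, pl in enumerate(table.ploidies) if pl == 1]
        assert geno[:, hap_cols].max() <= 1  # dosage 0/1 only

    def test_fixed_frequency_sampling(self):
        p = small_params(t=0.0)
        rng = np.random.default_rng(2)
        sf = sim.simulate_frequencies(p, rng)
        sf.freqs[:, :] = 1.0
        counts = sim.sample_allele_counts(sf, p, rng)
        assert (counts.alt == counts.called).all()

    def test_positions_unique_within_chromosome(self):
        p = small_params(theta_anc=0.01)
        sf = sim.simulate_frequencies(p, np.random.default_rng(3))
        assert len(np.unique(sf.pos)) == len(sf.pos)
        assert (np.diff(sf.pos) > 0).all()


class TestMomentRecovery:
    def test_no_divergence_fst_near_zero(self):
        p = small_params(t=0.0, theta_anc=0.02)
        rng = np.random.default_rng(4)
        sf = sim.simulate_frequencies(p, rng)
        counts = sim.sample_allele_counts(sf, p, rng)
        num, den = ds.site_fst_components(
            counts.alt[:, 0], counts.called[:, 0],
            counts.alt[:, 1], counts.called[:, 1])
        ok = np.isfinite(num) & (den > 0)
        assert abs(num[ok].sum() / den[ok].sum()) < 0.02

    def test_sitewise_fst_recovers_f_exp_per_class(self):
        """Site-averaged Hudson F_ST per window class → F_exp (±0.02 at
        ≥5×10⁴ sites per class)."""
        cls = sim.block_classes(200, [(0, 100)], "barrier")
        p = small_params(chrom_lengths={"c1": 4_000_000}, theta_anc=0.08,
                         window_classes=cls, gene_flow=0.5, t=1200.0,
                         linked_selection=1.0,
                         samples={"p1": (30, 10), "p2": (30, 10)})
        rng = np.random.default_rng(5)
        sf = sim.simulate_frequencies(p, rng)
        counts = sim.sample_allele_counts(sf, p, rng)
        num, den = ds.site_fst_components(
            counts.alt[:, 0], counts.called[:, 0],
            counts.alt[:, 1], counts.called[:, 1])
        cls_site = sf.truth["class"].to_numpy()[sf.win_row]
        for label in ("barrier", "background"):
            m = (cls_site == label) & np.isfinite(num) & (den > 0)
            assert m.sum() > 5e4
            got = num[m].sum() / den[m].sum()
            f_exp = sf.truth.loc[sf.truth["class"] == label, "F_exp"].iloc[0]
            assert got == pytest.approx(f_exp, abs=0.02)

    def test_linked_selection_reduces_diversity_proportionally(self):
        cls = sim.block_classes(100, [(0, 50)], "barrier")
        p = small_params(chrom_lengths={"c1": 2_000_000}, theta_anc=0.05,
                         window_classes=cls, t=0.0, linked_selection=0.2)
        rng = np.random.default_rng(6)
        sf = sim.simulate_frequencies(p, rng)
        counts = sim.sample_allele_counts(sf, p, rng)
        pi = ds.site_pi(counts.alt[:, 0], counts.called[:, 0])
        cls_site = sf.truth["class"].to_numpy()[sf.win_row]
        # per-base diversity ratio ≈ λ: both site density and (here t=0)
        # per-site diversity are scaled via the site count
        per_base = {}
        for label in ("barrier", "background"):
            n_bp = sf.truth.loc[sf.truth["class"] == label,
                                "end"].sum() - sf.truth.loc[
                sf.truth["class"] == label, "start"].sum()
            per_base[label] = np.nansum(pi[cls_site == label]) / n_bp
        assert per_base["barrier"] / per_base["background"] == \
            pytest.approx(0.2, abs=0.04)

    def test_dxy_composition_matches_analytic_expectation(self):
        """E[d_XY] ≈ π_anc·λ + 2µ·t_eff per window class."""
        cls = sim.block_classes(200, [(0, 100)], "barrier")
        p = small_params(chrom_lengths={"c1": 4_000_000}, theta_anc=0.02,
                         window_classes=cls, t=2000.0, mu=3e-7,
                         gene_flow=0.5, linked_selection=0.25)
        rng = np.random.default_rng(7)
        sf = sim.simulate_frequencies(p, rng)
        dxy = ds.site_dxy(sf.freqs[:, 0], sf.freqs[:, 1])
        cls_site = sf.truth["class"].to_numpy()[sf.win_row]
        het = _sfs_mean_het()
        pi_anc = p.theta_anc * het
        for label, lam, t_eff in (("barrier", 0.25, 2000.0),
                                  ("background", 1.0, 1000.0)):
            n_bp = 100 * 20_000
            got = dxy[cls_site == label].sum() / n_bp
            expected = pi_anc * lam + 2 * p.mu * t_eff
            assert got == pytest.approx(expected, rel=0.1)


def _sfs_mean_het():
    """Mean 2p(1−p) under the generator's discretized 1/k neutral SFS."""
    k = np.arange(1, 200)
    w = (1 / k) / (1 / k).sum()
    pgrid = k / 200
    return float(np.sum(w * 2 * pgrid * (1 - pgrid)))


class TestOutputs:
    def test_truth_bed_counts_barrier_windows(self, tmp_path):
        cls = sim.block_classes(50, [(5, 4), (30, 3)], "barrier")
        p = small_params(window_classes=cls)
        rng = np.random.default_rng(8)
        sf = sim.simulate_frequencies(p, rng)
        table, geno = sim.sample_genotypes(sf, p, rng)
        paths = sim.write_outputs(tmp_path / "o", sf, table, geno, p)
        bed = open(paths["truth_bed"]).read().strip().splitlines()
        assert len(bed) == 7

    def test_empty_simulation_writes_valid_header_only_vcf(self, tmp_path):
        p = small_params(theta_anc=0.0, mu=0.0)
        rng = np.random.default_rng(9)
        sf = sim.simulate_frequencies(p, rng)
        assert len(sf) == 0
        table, geno = sim.sample_genotypes(sf, p, rng)
        paths = sim.write_outputs(tmp_path / "o", sf, table, geno, p)
        from divscan.variants import read_sites_table
        sites = read_sites_table(paths["vcf"], table)
        assert len(sites) == 0
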