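"""Generator contracts: determinism, planted structure, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyploid_diel.simulate import (
    SimDesign,
    draw_library_sizes,
    generate_bundle,
    generate_parental_genomes,
    make_gene_truth,
    simulate_diel_counts,
    simulate_fragments,
    simulate_pileups,
)


class TestParentalGenomes:
    def test_zero_rate_gives_identical_sequences(self):
        ref, div, snps = generate_parental_genomes(4, 0.0, seed=1)
        assert ref == div
        assert snps.empty

    def test_snp_count_within_binomial_99_interval(self):
        length, rate = 10_000, 0.01
        _, _, snps = generate_parental_genomes(length, rate, seed=1)
        lo, hi = stats.binom.ppf([0.005, 0.995], length, rate)
        assert lo <= len(snps) <= hi

    def test_diverged_differs_exactly_at_snp_positions(self):
        ref, div, snps = generate_parental_genomes(5000, 0.02, seed=3)
        diff = {i + 1 for i, (a, b) in enumerate(zip(ref, div)) if a != b}
        assert diff == set(snps["pos"])
        assert (snps["ref"] != snps["alt"]).all()

    def test_same_seed_reproduces(self):
        a = generate_parental_genomes(2000, 0.01, seed=7)
        b = generate_parental_genomes(2000, 0.01, seed=7)
        assert a[0] == b[0] and a[1] == b[1]
        pd.testing.assert_frame_equal(a[2], b[2])

    @pytest.mark.parametrize("length,rate", [(0, 0.01), (10, -0.1), (10, 1.0)])
    def test_invalid_arguments_raise(self, length, rate):
        with pytest.raises(ValueError):
            generate_parental_genomes(length, rate, seed=0)


class TestPileups:
    def test_noiseless_snp_site_is_homogenic_and_heterogenic(self):
        ref, _, snps = generate_parental_genomes(2000, 0.02, seed=5)
        pile = simulate_pileups(ref, snps, depth=10, error_rate=0.0, seed=6)
        snp_rows = pile[pile["is_true_snp"]]
        bases = list("ACGT")
        for _, row in snp_rows.head(20).iterrows():
            p2 = np.array([row[f"p2_{b}"] for b in bases])
            hyb = np.array([row[f"hyb_{b}"] for b in bases])
            ref_i = bases.index(row["ref"])
            assert p2.sum() == 10 and p2[ref_i] == 0 and p2.max() == 10
            assert hyb[ref_i] > 0 and (hyb > 0).sum() == 2

    def test_noiseless_decoy_site_is_all_reference(self):
        ref, _, snps = generate_parental_genomes(2000, 0.02, seed=5)
        pile = simulate_pileups(ref, snps, depth=10, error_rate=0.0, seed=6)
        decoys = pile[~pile["is_true_snp"]]
        bases = list("ACGT")
        for _, row in decoys.head(20).iterrows():
            ref_b = row["ref"]
            assert row[f"p2_{ref_b}"] == 10 and row[f"hyb_{ref_b}"] == 10

    def test_error_rate_recovered_by_law_of_large_numbers(self):
        # progenitor-2 reads at decoy sites: every non-ref base is an error
        ref, _, snps = generate_parental_genomes(30_000, 0.005, seed=8)
        pile = simulate_pileups(ref, snps, depth=50, error_rate=0.01, seed=9)
        decoys = pile[~pile["is_true_snp"]]
        assert len(decoys) >= 1000
        bases = list("ACGT")
        p2 = decoys[[f"p2_{b}" for b in bases]].to_numpy()
        ref_i = pd.Categorical(decoys["ref"], categories=bases).codes
        nonref = p2.sum(axis=1) - p2[np.arange(len(decoys)), ref_i]
        assert np.mean(nonref) / 50 == pytest.approx(0.01, rel=0.15)


class TestFragments:
    def test_noiseless_mismatch_counts(self):
        frag = simulate_fragments(5000, 1.5, 0.0, seed=10)
        own = np.where(frag["true_origin"] == "Bd", frag["mm_bd"], frag["mm_bs"])
        other = np.where(frag["true_origin"] == "Bd", frag["mm_bs"], frag["mm_bd"])
        assert (own == 0).all()
        assert (other == frag["n_snps"]).all()

    def test_zero_snp_fragment_is_uninformative(self):
        frag = simulate_fragments(5000, 1.0, 0.0, seed=11)
        zero = frag[frag["n_snps"] == 0]
        assert (zero["mm_bd"] == 0).all() and (zero["mm_bs"] == 0).all()

    def test_tie_fraction_matches_poisson_zero(self):
        lam = 1.5
        frag = simulate_fragments(10_000, lam, 0.005, seed=12)
        tied = (frag["mm_bd"] == frag["mm_bs"]).mean()
        assert tied == pytest.approx(np.exp(-lam), abs=0.02)


class TestDielCounts:
    def test_degenerate_dispersion_is_poisson_like(self):
        design = SimDesign(n_genes=200, seed=1)
        truth = make_gene_truth(design, frac_rhythmic=0.0, dispersion=0.0,
                                base_range=(100.0, 100.0), bias_fold=1.0,
                                category_probs={"balance_retention": 1.0})
        libs = pd.Series(1_000_000, index=draw_library_sizes(design).index)
        counts, _ = simulate_diel_counts(design, truth, libs)
        vals = counts["P1"].to_numpy().ravel()
        assert vals.mean() == pytest.approx(100, rel=0.02)
        assert vals.var() == pytest.approx(100, rel=0.15)

    def test_replicate_mean_peaks_at_planted_phase(self):
        # peak time point carries the maximal replicate-mean for >= 95% of genes
        design = SimDesign(n_genes=300, seed=2)
        truth = make_gene_truth(design, frac_rhythmic=1.0,
                                amplitude_range=(0.5, 1.0), dispersion=0.05,
                                base_range=(200.0, 2000.0))
        truth["phase_P1"] = 10.0
        libs = draw_library_sizes(design)
        counts, meta = simulate_diel_counts(design, truth, libs)
        m = meta.set_index("sample_id")
        p1_cols = [c for c in counts["P1"].columns]
        hours = sorted(m.loc[p1_cols, "clock_hour"].unique())
        means = np.stack(
            [counts["P1"][[c for c in p1_cols if m.loc[c, "clock_hour"] == h]]
             .mean(axis=1).to_numpy() for h in hours], axis=1)
        argmax_hour = np.array(hours)[means.argmax(axis=1)]
        # MC-derived level: neighbours 4 h away sit at 1 + A/2 of baseline,
        # so low-amplitude genes lose the argmax to replicate noise ~8% of
        # the time at dispersion 0.05
        assert (argmax_hour == 10.0).mean() >= 0.9

    def test_planted_bias_retention_ratio_near_two(self):
        design = SimDesign(n_genes=400, seed=3)
        truth = make_gene_truth(design, frac_rhythmic=0.0, dispersion=0.02,
                                base_range=(500.0, 500.0), bias_fold=2.0,
                                category_probs={"bias_retention": 1.0})
        libs = pd.Series(1_000_000, index=draw_library_sizes(design).index)
        counts, _ = simulate_diel_counts(design, truth, libs)
        pos = truth["bias_sign"].to_numpy() > 0
        for hi, lo in (("P1", "P2"), ("BdSub", "BsSub")):
            ratio = (counts[hi].mean(axis=1) / counts[lo].mean(axis=1)).to_numpy()
            assert np.median(ratio[pos]) == pytest.approx(2.0, rel=0.1)
            assert np.median(ratio[~pos]) == pytest.approx(0.5, rel=0.1)

    def test_amplitude_above_one_raises(self):
        design = SimDesign(n_genes=10, seed=4)
        truth = make_gene_truth(design)
        truth.loc[0, "amplitude"] = 1.5
        libs = draw_library_sizes(design)
        with pytest.raises(ValueError, match="amplitude"):
            simulate_diel_counts(design, truth, libs)

    def test_nb_mean_variance_calibration(self):
        # empirical mean/variance track mu and mu + alpha*mu^2 within 5%
        design = SimDesign(n_genes=10, seed=5)
        rng_mu, alpha, n = 500.0, 0.1, 10_000
        from polyploid_diel.simulate import _nb_draw
        rng = np.random.default_rng(6)
        draws = _nb_draw(rng, np.full(n, rng_mu), np.full(n, alpha))
        assert draws.mean() == pytest.approx(rng_mu, rel=0.05)
        assert draws.var() == pytest.approx(rng_mu + alpha * rng_mu**2, rel=0.05)


class TestBundle:
    def test_seed_determinism_of_full_bundle(self):
        d = SimDesign(n_genes=50, seed=9)
        b1 = generate_bundle(d, genome_length=3000, n_fragments=500)
        b2 = generate_bundle(d, genome_length=3000, n_fragments=500)
        assert b1.reference == b2.reference and b1.diverged == b2.diverged
        pd.testing.assert_frame_equal(b1.snps, b2.snps)
        pd.testing.assert_frame_equal(b1.fragments, b2.fragments)
        pd.testing.assert_frame_equal(b1.truth, b2.truth)
        for ch in b1.counts:
            pd.testing.assert_frame_equal(b1.counts[ch], b2.counts[ch])

    def test_cross_references_resolve(self):
        d = SimDesign(n_genes=50, seed=9)
        b = generate_bundle(d, genome_length=3000, n_fragments=500)
        assert set(b.fragments["gene_id"]) <= set(b.truth["gene_id"])
        assert (b.snps["pos"] <= len(b.reference)).all()
        assert set(b.meta["sample_id"]) <= set(b.library_sizes.index)

    def test_design_validation(self):
        with pytest.raises(ValueError):
            SimDesign(n_replicates=1)
        with pytest.raises(ValueError):
            SimDesign(time_points_h=(2.0, 2.0, 10.0))
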