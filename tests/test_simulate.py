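import numpy as np
import pandas as pd
import pytest

from rohscan.genotypes import qc_filter, read_plink, read_pedigree, read_phenotypes
from rohscan.relationships import a_matrix
from rohscan.roh import detect_runs, summarize_catalog
from rohscan.simulate import (
    SimConfig,
    fixture_bundle,
    phenotyped_sows,
    sim_genotypes,
    sim_pedigree,
    sim_phenotypes,
    simulate,
)
from oracles import kinship

TINY = dict(
    n_founders=8, n_generations=2, offspring_per_generation=16,
    n_chromosomes=2, snps_per_chromosome=50, n_hys=6,
    planted_effects=(), seed=123,
)


class TestSimPedigree:
    def test_founders_only(self):
        ped = sim_pedigree(SimConfig(**{**TINY, "n_generations": 0}))
        assert len(ped) == 8
        assert all(s is None and d is None for s, d in zip(ped.sire, ped.dam))

    def test_determinism(self):
        p1 = sim_pedigree(SimConfig(**TINY))
        p2 = sim_pedigree(SimConfig(**TINY))
        assert p1.triples == p2.triples
        assert p1.sex == p2.sex

    def test_fullsib_line_builds_inbreeding_checked_by_kinship_oracle(self):
        cfg = SimConfig(**{**TINY, "mating_scheme": "partial_fullsib",
                           "inbreeding_intensity": 1.0, "n_generations": 3})
        ped = sim_pedigree(cfg)
        K = kinship(ped)
        F = 2 * np.diag(K) - 1
        last = [k for k, i in enumerate(ped.ids) if ped.generation[i] == 3]
        assert np.mean(F[last]) > 0
        np.testing.assert_allclose(np.diag(a_matrix(ped).values), 2 * np.diag(K))

    def test_intensity_knob_monotone_in_last_generation_inbreeding(self):
        means = []
        for intensity in (0.0, 0.5, 1.0):
            cfg = SimConfig(**{**TINY, "inbreeding_intensity": intensity,
                               "n_generations": 3, "seed": 5})
            ped = sim_pedigree(cfg)
            F = np.diag(a_matrix(ped).values) - 1
            last = [k for k, i in enumerate(ped.ids) if ped.generation[i] == 3]
            means.append(np.mean(F[last]))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > means[0]

    def test_too_few_founders_rejected(self):
        with pytest.raises(ValueError, match="founders"):
            SimConfig(**{**TINY, "n_founders": 2})


class TestSimGenotypes:
    def test_unsorted_pedigree_rejected(self):
        ped = sim_pedigree(SimConfig(**TINY))
        ped.sire = [len(ped) - 1] + ped.sire[1:]  # corrupt ordering
        with pytest.raises(ValueError, match="sorted"):
            sim_genotypes(ped, SimConfig(**TINY))

    def test_no_recombination_transmits_intact_founder_haplotypes(self):
        cfg = SimConfig(**{**TINY, "recomb_rate": 0.0, "n_generations": 3,
                           "inbreeding_intensity": 1.0})
        ped = sim_pedigree(cfg)
        gd, H = sim_genotypes(ped, cfg, return_haplotypes=True)
        founders = [k for k in range(len(ped)) if ped.sire[k] is None]
        founder_haps = {H[k, h].tobytes() for k in founders for h in range(2)}
        chrom = gd.markers["chromosome"].to_numpy()
        bounds = [np.flatnonzero(chrom == c) for c in dict.fromkeys(chrom)]
        for k in range(len(ped)):
            if ped.sire[k] is None:
                continue
            for h in range(2):
                for idx in bounds:
                    # per-chromosome haplotype is an intact copy of some
                    # founder chromosome
                    seg = H[k, h, idx]
                    assert any(
                        np.array_equal(seg, H[f, hh, idx])
                        for f in founders for hh in range(2)
                    )

    def test_mendelian_consistency_every_locus(self):
        cfg = SimConfig(**TINY)
        ped = sim_pedigree(cfg)
        gd = sim_genotypes(ped, cfg)
        feasible = {
            (0, 0): {0}, (0, 1): {0, 1}, (0, 2): {1},
            (1, 1): {0, 1, 2}, (1, 2): {1, 2}, (2, 2): {2},
        }
        for k in range(len(ped)):
            s, d = ped.sire[k], ped.dam[k]
            if s is None or d is None:
                continue
            key = np.minimum(gd.calls[s], gd.calls[d]), np.maximum(gd.calls[s], gd.calls[d])
            for j in range(gd.n_markers):
                assert gd.calls[k, j] in feasible[(int(key[0][j]), int(key[1][j]))]

    def test_inbred_line_has_more_roh_coverage_than_random_mating(self):
        covs = {}
        for scheme, intensity in (("random", 0.0), ("partial_fullsib", 1.0)):
            cfg = SimConfig(**{**TINY, "mating_scheme": scheme,
                               "inbreeding_intensity": intensity,
                               "n_generations": 4, "seed": 31})
            out = simulate(cfg)
            runs = detect_runs(out.genotypes, min_snps=16)
            covs[scheme] = summarize_catalog(runs, out.genotypes)["coverage_mean"]
        assert covs["partial_fullsib"] > covs["random"]


class TestSimPhenotypes:
    def test_degenerate_variances_give_exact_parity_effects(self):
        cfg = SimConfig(**{**TINY,
                           "varcomp_true": dict(sigma2_a=0, sigma2_p=0,
                                                sigma2_h=0, sigma2_e=0),
                           "het_slope_true": 0.0, "nba_loss_mean": 0.0,
                           "round_phenotypes": False})
        ped = sim_pedigree(cfg)
        gd = sim_genotypes(ped, cfg)
        phen, truth = sim_phenotypes(ped, gd, cfg)
        for _, r in phen.records.iterrows():
            assert r.tnb == pytest.approx(cfg.parity_effects[r.parity - 1])

    def test_nba_never_exceeds_tnb(self):
        out = simulate(SimConfig(**{**TINY, "seed": 77}))
        assert (out.phenotypes.records["nba"] <= out.phenotypes.records["tnb"]).all()

    def test_planted_carrier_truth_agrees_with_genotypes(self, small_sim):
        cfg, out = small_sim
        (key,) = out.truth["carriers"].keys()
        chrom, start, end = key
        mk = out.genotypes.markers
        idx = np.flatnonzero(
            (mk["chromosome"] == chrom)
            & (mk["position_bp"] >= start) & (mk["position_bp"] <= end)
        )
        hom = (out.genotypes.calls[:, idx] != 1).all(axis=1)
        expected = dict(zip(out.genotypes.samples, hom.astype(int)))
        assert out.truth["carriers"][key] == expected
        freq = np.mean(list(expected.values()))
        assert 0.1 < freq < 0.7  # near the 0.35 target, drift allowed

    def test_planted_effect_shows_in_raw_group_means(self):
        # quiet background: group-mean difference must approach the effect
        cfg = SimConfig(
            n_founders=16, n_generations=3, offspring_per_generation=80,
            n_chromosomes=3, snps_per_chromosome=60, n_hys=5,
            varcomp_true=dict(sigma2_a=0.01, sigma2_p=0.01, sigma2_h=0.01,
                              sigma2_e=0.05),
            het_slope_true=0.0, round_phenotypes=False,
            planted_effects=(("1", 10_000_000, 70_000_000, -0.6),),
            planted_carrier_freq=0.4, seed=21,
        )
        out = simulate(cfg)
        key = ("1", 10_000_000, 70_000_000)
        carriers = out.truth["carriers"][key]
        rec = out.phenotypes.records
        is_car = rec["sow"].map(carriers) == 1
        diff = rec.loc[is_car, "tnb"].mean() - rec.loc[~is_car, "tnb"].mean()
        assert diff == pytest.approx(-0.6, abs=0.15)

    def test_breeding_value_variance_tracks_pedigree_diagonal(self):
        # across replicates, Var(u_i) ~= sigma2_a * A_ii
        cfg0 = SimConfig(**{**TINY, "n_generations": 3,
                            "inbreeding_intensity": 1.0})
        ped = sim_pedigree(cfg0)
        gd = sim_genotypes(ped, cfg0)
        Adiag = np.diag(a_matrix(ped).values)
        us = []
        for seed in range(60):
            cfg = SimConfig(**{**TINY, "n_generations": 3,
                               "inbreeding_intensity": 1.0, "seed": seed})
            _, truth = sim_phenotypes(ped, gd, cfg)
            us.append([truth["u"][i] for i in ped.ids])
        U = np.array(us)
        ratio = U.var(axis=0, ddof=1) / (0.145 * Adiag)
        # Monte-Carlo noise at 60 replicates: check the mean ratio
        assert np.mean(ratio) == pytest.approx(1.0, abs=0.2)


class TestFixtureBundle:
    def test_files_round_trip_and_pass_qc(self, tmp_path):
        cfg = SimConfig(**TINY)
        paths = fixture_bundle(cfg, tmp_path / "fx", binary=True)
        gd = read_plink(str(tmp_path / "fx" / "genotypes"), dialect="text")
        gdb = read_plink(str(tmp_path / "fx" / "genotypes"), dialect="binary")
        out = simulate(cfg)
        # binary dialect round-trips exactly; the text dialect reflects
        # markers whose counted allele never occurs (no allele reference)
        np.testing.assert_array_equal(gdb.calls, out.genotypes.calls)
        expected_text = out.genotypes.calls.copy()
        all_zero = (expected_text == 0).all(axis=0)
        expected_text[:, all_zero] = 2
        np.testing.assert_array_equal(gd.calls, expected_text)
        assert gd.samples == out.genotypes.samples
        ped = read_pedigree(paths["pedigree"])
        assert set(ped.ids) == set(out.pedigree.ids)
        phen = read_phenotypes(paths["phenotypes"])
        assert len(phen) == len(out.phenotypes)
        filtered = qc_filter(gd)
        assert filtered.n_samples == gd.n_samples
        assert filtered.n_markers == gd.n_markers

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(**TINY)
        fixture_bundle(cfg, tmp_path / "a")
        fixture_bundle(cfg, tmp_path / "b")
        for name in ("genotypes.ped", "genotypes.map", "pedigree.tsv",
                     "phenotypes.tsv", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()
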