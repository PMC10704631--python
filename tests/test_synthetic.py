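import numpy as np
import pandas as pd
import pytest

from strainshift.quantification import gene_copy_number
from strainshift.synthetic import (
    CommunityScenario,
    PlantedOg,
    SpeciesConfig,
    default_scenario,
    generate_species_model,
    simulate_all,
    simulate_allele_observations,
    simulate_community,
    simulate_gene_coverage,
    simulate_og_coverage,
    simulate_qpcr,
    write_allele_vcf,
)


def small_config(**kw):
    defaults = dict(
        species_id="spA",
        genome_length=100_000,
        n_genes=12,
        n_core_genes=10,
        n_variant_sites=50,
        n_strains=4,
    )
    defaults.update(kw)
    return SpeciesConfig(**defaults)


class TestGenerateSpeciesModel:
    def test_determinism(self):
        cfg = small_config()
        m1 = generate_species_model(cfg, np.random.default_rng(7))
        m2 = generate_species_model(cfg, np.random.default_rng(7))
        assert m1 == m2

    def test_core_flag_count(self):
        cfg = small_config(n_genes=10, n_core_genes=4)
        m = generate_species_model(cfg, np.random.default_rng(0))
        assert sum(1 for g in m.gene_catalog if g[3]) == 4

    def test_haplotype_lengths(self):
        cfg = small_config(n_variant_sites=100, n_strains=3)
        m = generate_species_model(cfg, np.random.default_rng(0))
        assert len(m.strains) == 3
        for s in m.strains:
            assert len(s.haplotype) == len(m.variant_sites) == 100

    def test_core_genes_span_position_range(self):
        cfg = small_config(n_core_genes=20, n_genes=20)
        m = generate_species_model(cfg, np.random.default_rng(0))
        starts = [g[1] for g in m.core_genes]
        assert min(starts) < 0.1 and max(starts) > 0.9

    def test_zero_core_genes_rejected(self):
        with pytest.raises(ValueError, match="core"):
            small_config(n_core_genes=0)

    def test_alleles_are_dna(self):
        m = generate_species_model(small_config(), np.random.default_rng(1))
        for pos, ref, alts in m.variant_sites:
            assert ref in "ACGT"
            assert all(a in "ACGT" and a != ref for a in alts)


class TestSimulateCommunity:
    def test_design_shape(self):
        sc = default_scenario(seed=1)
        _, samples, abun, _ = simulate_community(sc, np.random.default_rng(1))
        assert len(samples) == 30  # 5 locations x 3 colonies x 2 states
        assert len({s.colony_id for s in samples}) == 15
        assert abun.shape == (30, 4)

    def test_neutral_multiplier_no_noise(self):
        sc = CommunityScenario(
            species=[small_config(state_multiplier=1.0)],
            n_locations=2,
            colonies_per_location=2,
            colony_sigma=0.0,
        )
        _, samples, abun, _ = simulate_community(sc, np.random.default_rng(0))
        by_colony = {}
        for s in samples:
            by_colony.setdefault(s.colony_id, {})[s.state] = abun.loc[
                s.sample_id, "spA"
            ]
        for states in by_colony.values():
            assert states["nurse"] == pytest.approx(states["forager"])

    def test_zero_overlap_pools_disjoint(self):
        sc = CommunityScenario(
            species=[small_config()],
            strain_pool_overlap=0.0,
            n_locations=2,
            colonies_per_location=2,
        )
        _, samples, _, mix = simulate_community(sc, np.random.default_rng(0))
        state = {s.sample_id: s.state for s in samples}
        mix["state"] = mix["sample_id"].map(state)
        nurse = set(mix[mix["state"] == "nurse"]["strain_id"])
        forager = set(mix[mix["state"] == "forager"]["strain_id"])
        assert nurse.isdisjoint(forager)

    def test_full_overlap_pools_identical(self):
        sc = CommunityScenario(
            species=[small_config()],
            strain_pool_overlap=1.0,
            n_locations=2,
            colonies_per_location=2,
        )
        _, samples, _, mix = simulate_community(sc, np.random.default_rng(0))
        state = {s.sample_id: s.state for s in samples}
        mix["state"] = mix["sample_id"].map(state)
        nurse = set(mix[mix["state"] == "nurse"]["strain_id"])
        forager = set(mix[mix["state"] == "forager"]["strain_id"])
        assert nurse == forager

    def test_mixture_proportions_sum_to_one(self):
        sc = default_scenario(seed=2)
        _, _, _, mix = simulate_community(sc, np.random.default_rng(2))
        sums = mix.groupby(["sample_id", "species_id"])["proportion"].sum()
        assert np.allclose(sums, 1.0)


class TestGeneCoverage:
    def _model(self):
        return generate_species_model(small_config(), np.random.default_rng(0))

    def test_flat_when_ptr_one(self):
        m = self._model()
        cov = simulate_gene_coverage(
            m, {"s1": 50.0}, ptr=1.0, noise="none",
            rng=np.random.default_rng(0)
        )
        assert np.allclose(cov["coverage"], 50.0)

    def test_ptr_ratio_definition(self):
        m = self._model()
        cov = simulate_gene_coverage(
            m, {"s1": 20.0}, ptr=5.0, noise="none",
            rng=np.random.default_rng(0)
        )
        # expected: ter 20 at x=0.5, ori 100 at x=0/1
        from strainshift.synthetic import expected_gene_coverage

        assert expected_gene_coverage(0.0, 20.0, 5.0) == pytest.approx(100.0)
        assert expected_gene_coverage(0.5, 20.0, 5.0) == pytest.approx(20.0)
        assert cov["coverage"].max() <= 100.0 + 1e-9
        assert cov["coverage"].min() >= 20.0 - 1e-9

    def test_poisson_mean_within_one_percent(self):
        cfg = small_config(genome_length=10_000_000, n_genes=10_000,
                          n_core_genes=10_000, n_variant_sites=0)
        m = generate_species_model(cfg, np.random.default_rng(0))
        cov = simulate_gene_coverage(
            m, {"s1": 30.0}, ptr=1.0, noise="poisson",
            rng=np.random.default_rng(0)
        )
        assert cov["coverage"].mean() == pytest.approx(30.0, rel=0.01)

    def test_negative_abundance_rejected(self):
        m = self._model()
        with pytest.raises(ValueError, match="negative"):
            simulate_gene_coverage(m, {"s1": -1.0}, 2.0, "none",
                                   np.random.default_rng(0))


def single_strain_mixture(model, sample="s1"):
    return pd.DataFrame(
        {
            "sample_id": [sample],
            "species_id": [model.species_id],
            "strain_id": [model.strains[0].strain_id],
            "proportion": [1.0],
        }
    )


class TestAlleleObservations:
    def _model(self, **kw):
        return generate_species_model(small_config(**kw),
                                      np.random.default_rng(3))

    def test_single_strain_no_error_monomorphic(self):
        m = self._model()
        obs = simulate_allele_observations(
            m, single_strain_mixture(m), depth=100, error_rate=0.0,
            rng=np.random.default_rng(0)
        )
        per_site = obs.groupby("site")["allele"].nunique()
        assert (per_site == 1).all()
        # and the allele is the strain haplotype allele
        hap = dict(zip((v[0] for v in m.variant_sites), m.strains[0].haplotype))
        for row in obs.itertuples(index=False):
            assert row.allele == hap[row.site]

    def test_counts_sum_to_depth(self):
        m = self._model()
        obs = simulate_allele_observations(
            m, single_strain_mixture(m), depth=250, error_rate=0.01,
            rng=np.random.default_rng(0)
        )
        sums = obs.groupby("site")["count"].sum()
        assert (sums == 250).all()

    def test_two_strains_5050_expected_split(self):
        m = self._model(n_strains=2, n_variant_sites=40)
        mix = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "species_id": [m.species_id] * 2,
                "strain_id": [s.strain_id for s in m.strains],
                "proportion": [0.5, 0.5],
            }
        )
        obs = simulate_allele_observations(
            m, mix, depth=100_000, error_rate=0.0,
            rng=np.random.default_rng(0)
        )
        h1, h2 = (s.haplotype for s in m.strains)
        diff_sites = [
            v[0] for v, a, b in zip(m.variant_sites, h1, h2) if a != b
        ]
        assert diff_sites
        for site in diff_sites:
            counts = obs[obs["site"] == site]["count"]
            assert np.allclose(counts / 100_000, 0.5, atol=0.02)

    def test_error_rate_expectation(self):
        m = self._model(n_variant_sites=10)
        obs = simulate_allele_observations(
            m, single_strain_mixture(m), depth=1_000_000, error_rate=0.01,
            rng=np.random.default_rng(0)
        )
        hap = dict(zip((v[0] for v in m.variant_sites), m.strains[0].haplotype))
        errs = obs[
            obs.apply(lambda r: r["allele"] != hap[r["site"]], axis=1)
        ]
        freqs = errs["count"] / 1_000_000
        assert np.allclose(freqs.mean(), 0.01 / 3, rtol=0.1)

    def test_empty_mixture_rejected(self):
        m = self._model()
        with pytest.raises(ValueError, match="empty"):
            simulate_allele_observations(
                m, pd.DataFrame(columns=["sample_id", "strain_id",
                                         "proportion"]),
                100, 0.0, np.random.default_rng(0)
            )

    def test_vcf_round_trip(self, tmp_path):
        from strainshift.io_filters import read_allele_observations

        m = self._model(n_strains=3)
        mix = pd.DataFrame(
            {
                "sample_id": ["s1"] * 3 + ["s2"] * 3,
                "species_id": [m.species_id] * 6,
                "strain_id": [s.strain_id for s in m.strains] * 2,
                "proportion": [0.5, 0.3, 0.2, 0.1, 0.2, 0.7],
            }
        )
        obs = simulate_allele_observations(
            m, mix, depth=150, error_rate=0.005, rng=np.random.default_rng(5)
        )
        path = tmp_path / "obs.vcf"
        write_allele_vcf(obs, [m], path)
        back = read_allele_observations(path)
        key = ["species_id", "site", "sample_id", "allele"]
        a = obs[obs["count"] > 0].sort_values(key).reset_index(drop=True)
        b = back[back["count"] > 0].sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a[key + ["count"]], b[key + ["count"]])


class TestOgCoverage:
    def _setup(self, planted=(), overlap=0.0):
        sc = CommunityScenario(
            species=[small_config()],
            n_locations=2,
            colonies_per_location=2,
            colony_sigma=0.0,
            strain_pool_overlap=overlap,
            planted_differential_ogs=list(planted),
        )
        rng = np.random.default_rng(4)
        models, samples, abun, mix = simulate_community(sc, rng)
        og = simulate_og_coverage(
            models, abun, mix, sc.planted_differential_ogs, samples, rng
        )
        return models, samples, abun, mix, og

    def test_core_og_tracks_abundance(self):
        models, samples, abun, _, og = self._setup()
        core = og[og["is_core"]]
        for row in core.itertuples(index=False):
            assert row.coverage == pytest.approx(
                abun.loc[row.sample_id, row.species_id]
            )

    def test_absent_accessory_zero(self):
        models, samples, _, mix, og = self._setup(overlap=0.0)
        state = {s.sample_id: s.state for s in samples}
        present = set(mix[mix["sample_id"].map(state) == "nurse"]["strain_id"])
        absent_strains = [
            s for s in models[0].strains if s.strain_id not in present
        ]
        assert absent_strains
        for strain in absent_strains:
            for og_id in strain.accessory_ogs:
                sub = og[
                    (og["og_id"] == og_id)
                    & (og["sample_id"].map(state) == "nurse")
                ]
                assert np.allclose(sub["coverage"], 0.0)

    def test_planted_fold_exact(self):
        planted = [PlantedOg("spA", "spA:planted:x", "forager", 4.0)]
        models, samples, abun, _, og = self._setup(planted=planted)
        state = {s.sample_id: s.state for s in samples}
        sub = og[og["og_id"] == "spA:planted:x"].copy()
        sub["state"] = sub["sample_id"].map(state)
        sub["rel"] = sub["coverage"] / sub["sample_id"].map(
            lambda s: abun.loc[s, "spA"]
        )
        f = sub[sub["state"] == "forager"]["rel"].mean()
        n = sub[sub["state"] == "nurse"]["rel"].mean()
        assert f / n == pytest.approx(4.0)

    def test_unknown_planted_species_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            self._setup(planted=[PlantedOg("nope", "og", "forager", 2.0)])


class TestQpcr:
    def test_copies_one_gives_intercept(self):
        m = simulate_qpcr({"s1": 1.0}, -3.3, 38.0, 0.0,
                          np.random.default_rng(0))[0]
        assert m.ct_mean == pytest.approx(38.0)

    def test_hand_value(self):
        m = simulate_qpcr({"s1": 100.0}, -1.0, 10.0, 0.0,
                          np.random.default_rng(0))[0]
        assert m.ct_mean == pytest.approx(8.0)

    def test_noise_free_round_trip(self):
        copies = 5.5e5
        m = simulate_qpcr({"s1": copies}, -3.32, 38.0, 0.0,
                          np.random.default_rng(0))[0]
        assert gene_copy_number(m.ct_replicates, m.slope,
                                m.intercept) == pytest.approx(copies)

    def test_nonpositive_copies_rejected(self):
        with pytest.raises(ValueError):
            simulate_qpcr({"s1": 0.0}, -3.3, 38.0, 0.0,
                          np.random.default_rng(0))


class TestScenarioValidation:
    def test_error_rate_bounds(self):
        with pytest.raises(ValueError):
            CommunityScenario(species=[small_config()], sequencing_error=0.1)

    def test_ptr_bound(self):
        with pytest.raises(ValueError):
            CommunityScenario(species=[small_config()], ptr=0.5)

    def test_overlap_bounds(self):
        with pytest.raises(ValueError):
            CommunityScenario(species=[small_config()],
                              strain_pool_overlap=1.5)


class TestFullDeterminism:
    def test_simulate_all_byte_identical(self):
        sc1 = default_scenario(seed=9)
        sc2 = default_scenario(seed=9)
        b1 = simulate_all(sc1)
        b2 = simulate_all(sc2)
        for key in ("gene_coverage", "allele_observations", "og_coverage",
                    "true_abundance", "strain_mixture"):
            pd.testing.assert_frame_equal(b1[key], b2[key])
        assert b1["samples"] == b2["samples"]
        assert [m.ct_replicates for m in b1["qpcr"]] == [
            m.ct_replicates for m in b2["qpcr"]
        ]
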