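"""Synthetic-data generators: contracts, determinism, planted structure."""

import numpy as np
import pytest
from scipy import stats

from viroshot.annotation import top_hit_per_query, top_hit_source_distribution
from viroshot.assembly import assemble_greedy, parse_clone_id
from viroshot.compare import compare_pair
from viroshot.simulate import (
    CloneModel,
    GenomeModel,
    HitModel,
    generate_genomes,
    generate_library_pair,
    shear_and_clone,
    simulate_gradient,
    simulate_hit_table,
)


def _binom_ci(n, p, alpha=0.01):
    return (stats.binom.ppf(alpha / 2, n, p),
            stats.binom.ppf(1 - alpha / 2, n, p))


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

class TestGenomes:
    def test_degenerate_size_class(self):
        model = GenomeModel(size_classes=((30000, 30000, 1.0),), n_genomes=3)
        assert [len(g) for g in generate_genomes(model, 5)] == [30000] * 3

    def test_class_counts_within_binomial_ci(self):
        model = GenomeModel(n_genomes=400)
        genomes = generate_genomes(model, seed=1)
        for lo_bp, hi_bp, weight in model.size_classes:
            count = sum(lo_bp <= len(g) <= hi_bp for g in genomes)
            lo, hi = _binom_ci(400, weight)
            assert lo <= count <= hi

    def test_deterministic_given_seed(self):
        model = GenomeModel(n_genomes=5)
        assert generate_genomes(model, 7) == generate_genomes(model, 7)
        assert generate_genomes(model, 7) != generate_genomes(model, 8)

    def test_gc_fraction_respected(self):
        model = GenomeModel(size_classes=((50000, 50000, 1.0),),
                            n_genomes=2, gc_fraction=0.3)
        genomes = generate_genomes(model, 3)
        gc = sum(g.count("G") + g.count("C") for g in genomes) / 100000
        assert gc == pytest.approx(0.3, abs=0.02)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            GenomeModel(size_classes=((1000, 2000, 0.7),))


# ---------------------------------------------------------------------------
# clones and reads
# ---------------------------------------------------------------------------

class TestShearAndClone:
    def _genomes(self):
        return generate_genomes(
            GenomeModel(size_classes=((30000, 30000, 1.0),), n_genomes=20),
            seed=11)

    def test_pairing_contract(self):
        result = shear_and_clone(self._genomes(),
                                 CloneModel(paired_fraction=1.0), 10, seed=2)
        assert len(result.reads) == 20
        clones = {}
        for r in result.reads:
            ident = parse_clone_id(r.id)
            clones.setdefault((ident.library, ident.plate, ident.well),
                              set()).add(ident.direction)
        assert len(clones) == 10
        assert all(dirs == {"F", "R"} for dirs in clones.values())

    def test_insert_lengths_within_excised_band(self):
        result = shear_and_clone(self._genomes(), CloneModel(), 200, seed=3)
        assert all(1400 <= n <= 4000 for n in result.insert_lengths)

    def test_duplicate_clones_recorded_and_assembled(self):
        result = shear_and_clone(
            self._genomes(),
            CloneModel(paired_fraction=0.0, duplicate_clone_rate=0.1),
            100, seed=4)
        n_dup = len(result.duplicate_pairs)
        lo, hi = _binom_ci(99, 0.1)  # first clone can never duplicate
        assert lo <= n_dup <= hi
        assembled = assemble_greedy(result.reads)
        contig_of = {m: c.id for c in assembled.contigs
                     for m in c.member_ids}
        recovered = sum(
            contig_of.get(f"{a}.F") is not None
            and contig_of.get(f"{a}.F") == contig_of.get(f"{b}.F")
            for a, b in result.duplicate_pairs
        )
        assert recovered >= 0.95 * len(result.duplicate_pairs)

    def test_short_genomes_skipped_with_warning(self, caplog):
        genomes = ["ACGT" * 200, self._genomes()[0]]  # 800 bp < 4 kb insert
        with caplog.at_level("WARNING"):
            result = shear_and_clone(genomes, CloneModel(), 5, seed=1)
        assert "skipping" in caplog.text
        assert len(result.clone_ids) == 5

    def test_deterministic_given_seed(self):
        genomes = self._genomes()
        a = shear_and_clone(genomes, CloneModel(), 20, seed=9)
        b = shear_and_clone(genomes, CloneModel(), 20, seed=9)
        assert [(r.id, r.sequence) for r in a.reads] == \
            [(r.id, r.sequence) for r in b.reads]

    def test_insert_floor_validated(self):
        with pytest.raises(ValueError):
            CloneModel(insert_min_bp=50)


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

class TestHitTable:
    def test_zero_hit_rate_gives_empty_table(self):
        model = HitModel(hit_rate=0.0)
        table = simulate_hit_table([f"q{i}" for i in range(50)], model, seed=1)
        assert table.empty

    def test_single_category_closes_the_loop(self):
        model = HitModel(composition={"bacteriophage": 1.0})
        table = simulate_hit_table([f"q{i}" for i in range(1000)], model,
                                   seed=2)
        top = top_hit_per_query(table)
        assert len(top) == 1000
        assert (top["source_category"] == "bacteriophage").all()

    def test_survey_like_composition_recovered_within_binomial_ci(self):
        model = HitModel()
        n = 881
        table = simulate_hit_table([f"q{i:04d}" for i in range(n)], model,
                                   seed=7)
        dist = top_hit_source_distribution(top_hit_per_query(table),
                                           threshold=np.inf, n_queries=n)
        checks = {
            "bacteria": 0.153,
            "no_hit": 0.743,
            "eukaryote": 0.011,
        }
        checks["virus"] = 0.0771 + 0.0049
        observed_virus = (dist.get("bacteriophage", 0)
                          + dist.get("eukaryotic_virus", 0))
        for cat, p in checks.items():
            got = observed_virus if cat == "virus" else dist.get(cat, 0.0)
            lo, hi = _binom_ci(n, p)
            assert lo <= round(got * n) <= hi, cat

    def test_composition_chisquare_not_rejected_at_n5000(self):
        composition = {"bacteriophage": 0.3, "bacteria": 0.5,
                       "eukaryote": 0.2}
        model = HitModel(composition=composition)
        n = 5000
        table = simulate_hit_table([f"q{i:05d}" for i in range(n)], model,
                                   seed=0)
        top = top_hit_per_query(table)
        counts = top["source_category"].value_counts()
        observed = [counts.get(c, 0) for c in composition]
        expected = [n * p for p in composition.values()]
        assert stats.chisquare(observed, expected).pvalue > 0.01

    def test_virus_descriptions_carry_keywords(self):
        from viroshot.annotation import keyword_virus_flag

        model = HitModel(composition={"bacteriophage": 0.5,
                                      "eukaryotic_virus": 0.5})
        table = simulate_hit_table([f"q{i}" for i in range(50)], model, seed=3)
        assert all(keyword_virus_flag(d)[0]
                   for d in table["subject_description"])

    def test_deterministic_given_seed(self):
        model = HitModel()
        a = simulate_hit_table([f"q{i}" for i in range(100)], model, seed=5)
        b = simulate_hit_table([f"q{i}" for i in range(100)], model, seed=5)
        assert a.equals(b)

    def test_invalid_composition_rejected(self):
        with pytest.raises(ValueError):
            HitModel(composition={"bacteriophage": 0.5})


# ---------------------------------------------------------------------------
# gradient
# ---------------------------------------------------------------------------

class TestGradient:
    def test_concentration_peaks_in_stated_fractions(self):
        fractions = simulate_gradient(seed=1)
        top = max(fractions, key=lambda f: f.vlp_per_ml)
        assert top.index in {1, 2, 3, 4}

    def test_densities_increase_down_the_gradient(self):
        fractions = simulate_gradient(seed=2)
        densities = [f.density for f in fractions]
        assert densities == sorted(densities)

    def test_zero_noise_reproduces_planted_density_exactly(self):
        fractions = simulate_gradient(seed=3, mass_noise_sd_g=0.0,
                                      density_range=(1.44, 1.66),
                                      n_fractions=12)
        assert fractions[0].density == pytest.approx(1.44, abs=1e-12)
        assert fractions[-1].density == pytest.approx(1.66, abs=1e-12)

    def test_deterministic_given_seed(self):
        assert simulate_gradient(seed=4) == simulate_gradient(seed=4)

    def test_requires_at_least_one_fraction(self):
        with pytest.raises(ValueError):
            simulate_gradient(n_fractions=0)


# ---------------------------------------------------------------------------
# library pairs
# ---------------------------------------------------------------------------

class TestLibraryPair:
    def test_fully_shared_pair_is_roughly_symmetric(self):
        pair = generate_library_pair(1.0, seed=5)
        res_ab = compare_pair(pair.profile_a, pair.profile_b,
                              pair.hits_b_into_a, pair.hits_a_into_b)
        res_ba = compare_pair(pair.profile_b, pair.profile_a,
                              pair.hits_a_into_b, pair.hits_b_into_a)
        assert res_ab.pct_query == pytest.approx(res_ba.pct_ref, abs=1e-9)
        assert abs(res_ab.hits_per_100 - res_ba.hits_per_100) < 15.0

    def test_disjoint_pools_give_no_hits(self):
        pair = generate_library_pair(0.0, seed=6)
        assert len(pair.hits_a_into_b) == 0
        assert len(pair.hits_b_into_a) == 0

    def test_hits_increase_with_shared_fraction(self):
        quarter = generate_library_pair(0.25, seed=7)
        half = generate_library_pair(0.5, seed=7)
        n_quarter = quarter.hits_a_into_b["query_id"].nunique()
        n_half = half.hits_a_into_b["query_id"].nunique()
        assert n_half > n_quarter

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            generate_library_pair(1.5)
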