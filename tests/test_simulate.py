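"""Synthetic-data generator: genealogies, SMM mutation, SNP placement,
scenario sampling and reproducibility."""
import numpy as np
import pytest

from ylineage.haplogroups import assign_haplogroup
from ylineage.io import apply_exclusions, write_samples
from ylineage.simulate import (
    LineageSpec,
    SimScenario,
    mutate_str,
    place_snps,
    simulate_dataset,
    simulate_genealogy,
    table1_like_scenario,
)
from ylineage.types import STRHaplotype

LOCI = [f"L{i}" for i in range(15)]
FOUNDER = STRHaplotype({l: 13 for l in LOCI})


class TestGenealogy:
    def test_star_branch_lengths(self):
        g = simulate_genealogy(3, "star", age_years=2500, gen_years=25, seed=0)
        assert g.n_leaves == 3
        assert all(g.branch_length(i) == 100.0 for i in range(3))
        assert g.root_age_generations == 100.0

    def test_coalescent_pair_structure(self):
        g = simulate_genealogy(2, "coalescent", age_years=5000, gen_years=25, seed=1)
        assert g.n_leaves == 2
        assert g.parent[0] == g.parent[1] == g.root
        assert g.root_age_generations == pytest.approx(200.0)

    def test_coalescent_root_is_mrca_at_requested_age(self):
        g = simulate_genealogy(20, "coalescent", age_years=7000, gen_years=25, seed=2)
        assert g.root_age_generations == pytest.approx(280.0)
        assert (np.sort(g.node_time[20:]) <= 280.0 + 1e-9).all()

    def test_same_seed_identical(self):
        g1 = simulate_genealogy(10, "coalescent", 7000, 25, seed=42)
        g2 = simulate_genealogy(10, "coalescent", 7000, 25, seed=42)
        assert (g1.parent == g2.parent).all()
        assert (g1.node_time == g2.node_time).all()

    def test_invalid_model(self):
        with pytest.raises(ValueError, match="model"):
            simulate_genealogy(5, "bogus", 1000, 25, seed=0)

    def test_too_few_lineages(self):
        with pytest.raises(ValueError):
            simulate_genealogy(1, "star", 1000, 25, seed=0)


class TestMutation:
    def test_zero_rates_leaves_equal_founder(self):
        g = simulate_genealogy(5, "star", 5000, 25, seed=0)
        leaves = mutate_str(g, {l: 0.0 for l in LOCI}, FOUNDER, seed=0)
        assert all(h == FOUNDER for h in leaves)

    def test_star_mean_steps_matches_closed_form(self):
        """Under a star of age T the net allele displacement per locus is
        Skellam(lam/2, lam/2) with lam = rate * T/gen, so
        E|steps| = lam e^-lam (I0(lam) + I1(lam)) per locus — approximately
        lam itself when back-mutations are rare."""
        from scipy.special import iv

        T, gen, rate = 7000.0, 25.0, 6.9e-4
        n = 500
        lam = rate * T / gen
        g = simulate_genealogy(n, "star", T, gen, seed=3)
        leaves = mutate_str(g, {l: rate for l in LOCI}, FOUNDER, seed=3)
        steps = np.array([
            sum(abs(int(h.get(l)) - 13) for l in LOCI) for h in leaves
        ])
        per_locus = lam * np.exp(-lam) * (iv(0, lam) + iv(1, lam))
        expected = len(LOCI) * per_locus
        se = np.sqrt(len(LOCI) * lam / n)  # Poisson variance bounds Var|steps|
        assert abs(steps.mean() - expected) < 3 * se
        # and the small-rate linearisation is close at these parameters
        assert expected == pytest.approx(T / gen * rate * len(LOCI), rel=0.1)

    def test_allele_variance_tracks_rate_times_depth(self):
        """SMM: Var(leaf allele) ~= mutation rate x branch length, checked by
        Monte Carlo at one locus."""
        T, gen, rate = 50000.0, 25.0, 2e-3
        g = simulate_genealogy(2000, "star", T, gen, seed=4)
        leaves = mutate_str(g, {"L0": rate}, STRHaplotype({"L0": 30}), seed=4)
        vals = np.array([int(h.get("L0")) for h in leaves], dtype=float)
        expected = rate * T / gen
        assert vals.var() == pytest.approx(expected, rel=0.15)

    def test_negative_rates_rejected(self):
        g = simulate_genealogy(3, "star", 1000, 25, seed=0)
        with pytest.raises(ValueError):
            mutate_str(g, {"L0": -1e-4}, STRHaplotype({"L0": 13}), seed=0)


class TestPlaceSnps:
    def test_qm3_states(self, tree):
        g = place_snps(tree, "Q-M3")
        assert g.state("M242") == "derived"
        assert g.state("M3") == "derived"
        assert g.state("L54") == "derived"
        for m in ("M19", "M194", "L663", "SA01", "L766", "M343", "M170", "NWT01"):
            assert g.state(m) == "ancestral"

    def test_r1b_states(self, tree):
        g = place_snps(tree, "R1b-M343")
        assert g.state("M343") == "derived" and g.state("M207") == "derived"
        assert g.state("M242") == "ancestral"

    def test_label_form_accepted(self, tree):
        assert place_snps(tree, "Q-NWT01 (xM265)").state("NWT01") == "derived"

    def test_unknown_lineage(self, tree):
        with pytest.raises(ValueError, match="unknown lineage"):
            place_snps(tree, "Z-M999")


class TestScenario:
    def test_shares_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimScenario(
                region_sizes={"R": 10},
                lineages=(LineageSpec("Q-M3", 4000.0, {"R": 0.5}),),
            )

    def test_byte_identical_reproducibility(self, tmp_path):
        sc = table1_like_scenario(seed=9)
        for name in ("a.tsv", "b.tsv"):
            ds, _ = simulate_dataset(sc)
            write_samples(ds, tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_region_sizes_respected_and_closure(self, tree):
        sc = table1_like_scenario(seed=13)
        ds, truth = simulate_dataset(sc)
        for region, n in sc.region_sizes.items():
            assert len(ds.by_region(region)) == n
        clean = apply_exclusions(ds)
        assert len(clean.str_samples()) == len(ds)  # complete haplotypes
        for s in clean.snp_samples():
            assert assign_haplogroup(s, tree).assigned

    def test_lineage_shares_within_binomial_error(self):
        """Aggregated across 20 replicate draws, each lineage's regional count
        stays within 4 binomial standard deviations of its share."""
        sc = table1_like_scenario(seed=0)
        reps = 20
        totals = {}
        for i in range(reps):
            ds, truth = simulate_dataset(table1_like_scenario(seed=1000 + i))
            for sid, lin in truth.lineage_of.items():
                region = next(s.region for s in ds.samples if s.id == sid)
                totals[(region, lin)] = totals.get((region, lin), 0) + 1
        for lin_spec in sc.lineages:
            for region, share in lin_spec.shares.items():
                n = sc.region_sizes[region] * reps
                observed = totals.get((region, lin_spec.name), 0)
                sd = np.sqrt(n * share * (1 - share))
                assert abs(observed - n * share) <= 4 * sd + 1e-9

    def test_empty_region_handled(self):
        sc = SimScenario(
            region_sizes={"R1": 6, "R2": 0},
            lineages=(LineageSpec("Q-M3", 4000.0, {"R1": 1.0, "R2": 1.0}),),
            seed=2,
        )
        ds, _ = simulate_dataset(sc)
        assert len(ds.by_region("R2")) == 0 and len(ds) == 6

    def test_truth_consistent_with_dataset(self):
        ds, truth = simulate_dataset(table1_like_scenario(seed=21))
        assert set(truth.lineage_of) == {s.id for s in ds.samples}
        df = truth.to_dataframe()
        assert len(df) == len(ds)
        assert set(truth.root_age_years) == set(truth.lineage_of.values())
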