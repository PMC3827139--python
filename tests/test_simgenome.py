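"""Generator checks: determinism, density landscape, meiosis, pedigrees."""

import numpy as np
import pytest
from scipy import stats

from haplomosaic import simgenome as sg


class TestBuildReference:
    def test_deterministic_given_seed(self, small_config):
        g1 = sg.build_reference(small_config)
        g2 = sg.build_reference(small_config)
        assert g1.chromosomes == g2.chromosomes
        assert [gm.exons for gm in g1.genes] == [gm.exons for gm in g2.genes]

    def test_gene_density_lower_in_pericentromere(self, small_config,
                                                  small_genome):
        ps, pe = small_genome.pericentromere["chr1"]
        inside = [g for g in small_genome.genes if ps <= g.start < pe]
        outside = [g for g in small_genome.genes
                   if g.start < ps or g.start >= pe]
        n = small_genome.length("chr1")
        per_100k_in = len(inside) / ((pe - ps) / 1e5)
        per_100k_out = len(outside) / ((n - (pe - ps)) / 1e5)
        assert per_100k_in < per_100k_out

    def test_zero_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            sg.SimulationConfig(chromosome_lengths={})

    def test_cds_are_clean_orfs(self, small_genome):
        from Bio.Seq import Seq
        for gene in small_genome.genes[:10]:
            cds = gene.cds_sequence(small_genome.chromosomes[gene.chrom])
            prot = str(Seq(cds).translate())
            assert prot[0] == "M" and prot.endswith("*")
            assert "*" not in prot[:-1]


class TestFounderVariants:
    def test_zero_intensity_gives_reference_founders(self, small_genome,
                                                     small_config):
        land = sg.DensityLandscape(
            {"chr1": [(0, small_genome.length("chr1"), 0.0)]})
        cfg = sg.SimulationConfig(
            seed=1, chromosome_lengths=small_config.chromosome_lengths,
            genetic_lengths_cm=small_config.genetic_lengths_cm,
            founders=small_config.founders, large_deletions_per_founder=0)
        panel = sg.simulate_founder_variants(small_genome, land,
                                             cfg.founders, 1, cfg)
        assert all(len(v) == 0 for v in panel.variants.values())

    def test_pairwise_count_matches_intensity(self, small_genome):
        # one 100 Kbp interval at 40 SNP/Kbp between two races:
        # expected pairwise differences 4000, Poisson 3 sigma band
        n = small_genome.length("chr1")
        land = sg.DensityLandscape({"chr1": [(0, 100_000, 40.0),
                                             (100_000, n, 0.0)]})
        cfg = sg.SimulationConfig(
            seed=3, chromosome_lengths={"chr1": n},
            genetic_lengths_cm={"chr1": 120.0},
            founders={"A": "Kafir", "B": "Durra"}, race_sharing=0.0,
            indel_fraction=0.0, large_deletions_per_founder=0)
        panel = sg.simulate_founder_variants(small_genome, land,
                                             cfg.founders, 3, cfg)
        from haplomosaic.haplotrace import pairwise_differences
        diffs = pairwise_differences(panel.variants["A"],
                                     panel.variants["B"])
        assert abs(len(diffs) - 4000) < 3 * np.sqrt(4000)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            sg.DensityLandscape({"chr1": [(0, 100, -1.0)]})

    def test_landscape_must_tile(self):
        with pytest.raises(ValueError):
            sg.DensityLandscape({"chr1": [(0, 100, 1.0), (150, 200, 1.0)]})


class TestMethylation:
    def test_probability_zero_leaves_genic_sites_unmethylated(
            self, small_genome, small_config):
        cfg = sg.SimulationConfig(
            seed=2, chromosome_lengths=small_config.chromosome_lengths,
            genetic_lengths_cm=small_config.genetic_lengths_cm,
            methylation_probs={"genic": 0.0, "intergenic": 1.0,
                               "pericentromeric": 1.0})
        gene = small_genome.genes[0]
        sites = [(gene.chrom, gene.start + 1)]
        m = sg.simulate_methylation(small_genome, sites, cfg)
        assert not m.is_methylated(gene.chrom, gene.start + 1)

    def test_site_outside_genome_rejected(self, small_genome, small_config):
        with pytest.raises(ValueError, match="outside genome"):
            sg.simulate_methylation(small_genome, [("chr1", 10**9)],
                                    small_config)

    def test_observed_fractions_within_binomial_ci(self, small_genome):
        cfg = sg.SimulationConfig(
            seed=5, chromosome_lengths={"chr1": small_genome.length("chr1")},
            genetic_lengths_cm={"chr1": 120.0},
            methylation_probs={"genic": 0.5, "intergenic": 0.95,
                               "pericentromeric": 0.95})
        rng = np.random.default_rng(5)
        # 1000 sites of each context
        genic, inter = [], []
        while len(genic) < 1000 or len(inter) < 1000:
            pos = int(rng.integers(0, small_genome.length("chr1")))
            ctx = small_genome.site_context("chr1", pos)
            if ctx == "genic" and len(genic) < 1000:
                genic.append(("chr1", pos))
            elif ctx == "intergenic" and len(inter) < 1000:
                inter.append(("chr1", pos))
        m = sg.simulate_methylation(small_genome, genic + inter, cfg)
        for sites, p in ((genic, 0.5), (inter, 0.95)):
            k = sum(m.is_methylated(*s) for s in sites)
            lo, hi = stats.binom.interval(0.99, len(sites), p)
            assert lo <= k <= hi


class TestMakeGamete:
    def test_zero_genetic_length_returns_parent_intact(self):
        line = sg.founder_line("A", {"chr1": 1000})
        rng = np.random.default_rng(0)
        gam = sg.make_gamete(line, {"chr1": 1000}, {"chr1": 0.0},
                             {"chr1": (400, 600)}, 0.05, rng)
        assert gam == {"chr1": [(0, 1000, "A")]}

    def test_crossover_count_is_poisson_mean(self):
        # 1 Morgan chromosome, 10,000 gametes: mean crossovers 1.0 +- 0.03
        lengths = {"chr1": 1_000_000}
        a = sg.founder_line("A", lengths)
        b = sg.founder_line("B", lengths)
        f1 = sg.LineGenome("F1", a.hap1, b.hap1)
        rng = np.random.default_rng(12)
        total_switches = 0
        n = 10_000
        for _ in range(n):
            gam = sg.make_gamete(f1, lengths, {"chr1": 100.0},
                                 {"chr1": (400_000, 600_000)}, 0.05, rng)
            total_switches += len(gam["chr1"]) - 1
        # observed founder switches undercount crossovers by the even/odd
        # cancellation only when breakpoints coincide; with continuous
        # positions each crossover switches the founder label
        assert abs(total_switches / n - 1.0) < 0.03

    def test_inbred_parent_gametes_identical_in_labels(self):
        line = sg.founder_line("A", {"chr1": 10_000})
        rng = np.random.default_rng(1)
        gam = sg.make_gamete(line, {"chr1": 10_000}, {"chr1": 200.0},
                             {"chr1": (4000, 6000)}, 0.05, rng)
        assert gam == {"chr1": [(0, 10_000, "A")]}

    def test_negative_genetic_length_rejected(self):
        line = sg.founder_line("A", {"chr1": 1000})
        with pytest.raises(ValueError):
            sg.make_gamete(line, {"chr1": 1000}, {"chr1": -1.0},
                           {"chr1": (400, 600)}, 0.05,
                           np.random.default_rng(0))


class TestBreed:
    def _config(self, seed=9):
        return sg.SimulationConfig(
            seed=seed, chromosome_lengths={"chr1": 1_000_000},
            genetic_lengths_cm={"chr1": 100.0},
            founders={"A": "Kafir", "B": "Durra", "C": "Caudatum"})

    def test_residual_heterozygosity_after_selfing(self):
        # F1 selfed to F8: expect (1/2)^7 residual heterozygosity per locus
        cfg = self._config()
        ped = sg.PedigreeGraph(
            founders=["A", "B"],
            crosses={"F1": ("A", "B", "F1"), "F8": ("F1", None, "ssd:7")})
        fracs = []
        for seed in range(300):
            cfg = self._config(seed)
            lines = sg.breed(ped, cfg_panel(cfg), cfg)
            line = lines["F8"]
            pts = np.linspace(0, 999_999, 200).astype(int)
            fracs.append(np.mean([line.founder_at("chr1", p, 1)
                                  != line.founder_at("chr1", p, 2)
                                  for p in pts]))
        # heterozygosity comes in large blocks, so the line-level variance
        # dominates: bound is ~3.3 sigma for 300 lines
        assert abs(np.mean(fracs) - 0.5 ** 7) < 0.008

    def test_selection_interval_fixed_to_stated_founder(self):
        cfg = self._config()
        ped = sg.PedigreeGraph(
            founders=["A", "B"],
            crosses={"F1": ("A", "B", "F1"), "BC1": ("F1", "B", "F1")},
            selection_loci=[("chr1", 200_000, 300_000, "A")])
        lines = sg.breed(ped, cfg_panel(cfg), cfg)
        bc1 = lines["BC1"]
        for pos in (200_000, 250_000, 299_999):
            assert bc1.founder_at("chr1", pos, 1) == "A"
            assert bc1.founder_at("chr1", pos, 2) == "A"

    def test_three_founder_pedigree_labels_closed(self):
        cfg = self._config()
        ped = sg.PedigreeGraph(
            founders=["A", "B", "C"],
            crosses={"F1": ("A", "B", "F1"),
                     "X": ("F1", "C", "F1"),
                     "term": ("X", None, "ssd:6")})
        lines = sg.breed(ped, cfg_panel(cfg), cfg)
        labels = {f for _, _, f in lines["term"].hap1["chr1"]}
        labels |= {f for _, _, f in lines["term"].hap2["chr1"]}
        assert labels <= {"A", "B", "C"}

    def test_cycle_raises(self):
        ped = sg.PedigreeGraph(founders=["A"],
                               crosses={"X": ("Y", "A", "F1"),
                                        "Y": ("X", "A", "F1")})
        with pytest.raises(ValueError, match="cycle or missing parent"):
            ped.topological_order()


def cfg_panel(cfg):
    """Empty variant panel over the configured founders (labels only)."""
    return sg.FounderPanel({f: r for f, r in cfg.founders.items()},
                           {f: [] for f in cfg.founders})


class TestRILs:
    def _parents(self, lengths):
        return (sg.founder_line("P1", lengths), sg.founder_line("P2", lengths))

    def test_f12_heterozygosity_below_point_one_percent(self):
        cfg = sg.SimulationConfig(seed=21,
                                  chromosome_lengths={"chr1": 1_000_000},
                                  genetic_lengths_cm={"chr1": 120.0})
        p1, p2 = self._parents(cfg.chromosome_lengths)
        rils = sg.generate_ril_population(p1, p2, 90, 12, 21, cfg)
        assert len(rils) == 90
        pts = np.linspace(0, 999_999, 100).astype(int)
        het = [r.founder_at("chr1", p, 1) != r.founder_at("chr1", p, 2)
               for r in rils for p in pts]
        # expectation (1/2)^11 ~ 0.049% of loci
        assert np.mean(het) < 0.001

    def test_f1_selfed_once_half_heterozygous(self):
        cfg = sg.SimulationConfig(seed=22,
                                  chromosome_lengths={"chr1": 1_000_000},
                                  genetic_lengths_cm={"chr1": 120.0})
        p1, p2 = self._parents(cfg.chromosome_lengths)
        rils = sg.generate_ril_population(p1, p2, 400, 2, 22, cfg)
        pts = np.linspace(0, 999_999, 50).astype(int)
        het = [r.founder_at("chr1", p, 1) != r.founder_at("chr1", p, 2)
               for r in rils for p in pts]
        assert abs(np.mean(het) - 0.5) < 0.05

    def test_seed_reproducibility(self):
        cfg = sg.SimulationConfig(seed=23,
                                  chromosome_lengths={"chr1": 500_000},
                                  genetic_lengths_cm={"chr1": 100.0})
        p1, p2 = self._parents(cfg.chromosome_lengths)
        r1 = sg.generate_ril_population(p1, p2, 10, 12, 23, cfg)
        r2 = sg.generate_ril_population(p1, p2, 10, 12, 23, cfg)
        assert [r.hap1 for r in r1] == [r.hap1 for r in r2]

    def test_identical_parents_rejected(self):
        cfg = sg.SimulationConfig(seed=1,
                                  chromosome_lengths={"chr1": 1000},
                                  genetic_lengths_cm={"chr1": 1.0})
        p1 = sg.founder_line("P1", cfg.chromosome_lengths)
        with pytest.raises(ValueError, match="differ"):
            sg.generate_ril_population(p1, p1, 5, 12, 1, cfg)

    def test_nonpositive_population_rejected(self):
        cfg = sg.SimulationConfig(seed=1,
                                  chromosome_lengths={"chr1": 1000},
                                  genetic_lengths_cm={"chr1": 1.0})
        p1, p2 = self._parents(cfg.chromosome_lengths)
        with pytest.raises(ValueError):
            sg.generate_ril_population(p1, p2, 0, 12, 1, cfg)


class TestConservation:
    def test_line_variants_equal_union_of_segment_founder_variants(
            self, small_panel, small_config):
        ped = sg.PedigreeGraph(
            founders=["A", "B"],
            crosses={"F1": ("A", "B", "F1"),
                     "L": ("F1", None, "ssd:10")})
        lines = sg.breed(ped, small_panel, small_config)
        line = lines["L"]
        got = line.variants(small_panel)
        expected = []
        for chrom in line.hap1:
            for s, e, f in line.hap1[chrom]:
                for v in small_panel.variants_in(f, chrom, s, e):
                    f2 = line.founder_at(chrom, v.pos, 2)
                    if small_panel.variant_at(f2, chrom, v.pos) == v:
                        expected.append(v)
        assert got == expected
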