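"""Pedigree simulator: founder panels, meiosis, truth tracts, scenarios."""

import numpy as np
import pytest
from scipy import stats

import rohkit as rk
from rohkit.simulate import (
    HapLabel,
    _truth_from_mosaics,
    meiosis,
)


class TestPanels:
    def test_no_variation_means_identical_founders(self):
        spec = rk.PopulationPanelSpec(
            scaffold_lengths={"s1": 100_000}, het_rate=0.0, fixed_diff_rate=0.0, seed=0
        )
        pool = rk.simulate_panels(spec)
        a = pool.render_diploid("x", pool.founder_mosaics("x", "A"))
        b = pool.render_diploid("y", pool.founder_mosaics("y", "B"))
        assert a.scaffolds == b.scaffolds
        assert set(a.scaffolds["s1"]) <= set("ACGT")  # fully homozygous

    def test_polymorphic_site_count_matches_poisson_rate(self):
        # sites are placed at 2*theta so an outbred individual hets at theta
        theta, L = 1e-3, 10_000_000
        spec = rk.PopulationPanelSpec(
            scaffold_lengths={"s1": L}, het_rate=theta, fixed_diff_rate=0.0, seed=1
        )
        pool = rk.simulate_panels(spec)
        pos, _ = pool.polymorphic_sites("s1")
        expect = 2 * theta * L
        assert abs(len(pos) - expect) < 4 * np.sqrt(expect)

    def test_diagnostic_site_count_matches_poisson_rate(self):
        d, L = 1e-4, 10_000_000
        spec = rk.PopulationPanelSpec(
            scaffold_lengths={"s1": L}, het_rate=0.0, fixed_diff_rate=d, seed=2
        )
        pool = rk.simulate_panels(spec)
        pos, a, b = pool.diagnostic_sites("s1")
        assert abs(len(pos) - d * L) < 4 * np.sqrt(d * L)
        assert (a != b).all()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            rk.PopulationPanelSpec(scaffold_lengths={"s1": 0})
        with pytest.raises(ValueError):
            rk.PopulationPanelSpec(scaffold_lengths={"s1": 10}, het_rate=1.5)


class TestMeiosis:
    def _founder_pair(self, L):
        h0 = [(0, L, HapLabel("f", 0, "A"))]
        h1 = [(0, L, HapLabel("f", 1, "A"))]
        return h0, h1

    def test_vanishing_rate_gives_intact_parental_haplotype(self):
        L = 1_000_000
        pair = self._founder_pair(L)
        gamete, bps = meiosis(pair, L, rk.RecombinationModel(1e-9), np.random.default_rng(0))
        assert len(bps) == 0
        assert gamete in (pair[0], pair[1])

    def test_mean_breakpoint_count_matches_rate(self):
        L = 100_000_000
        pair = self._founder_pair(L)
        model = rk.RecombinationModel(1.1)
        rng = np.random.default_rng(3)
        counts = [len(meiosis(pair, L, model, rng)[1]) for _ in range(4000)]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - 1.1) < 4 * se

    def test_breakpoints_uniform_on_scaffold(self):
        L = 100_000_000
        pair = self._founder_pair(L)
        model = rk.RecombinationModel(1.1)
        rng = np.random.default_rng(4)
        bps = np.concatenate(
            [meiosis(pair, L, model, rng)[1] for _ in range(3000)]
        )
        _, p = stats.kstest(bps / L, "uniform")
        assert p > 0.01

    def test_gamete_tiles_scaffold(self):
        L = 10_000_000
        pair = self._founder_pair(L)
        model = rk.RecombinationModel(50.0)  # many crossovers
        gamete, _ = meiosis(pair, L, model, np.random.default_rng(5))
        assert gamete[0][0] == 0 and gamete[-1][1] == L
        for (s0, e0, _), (s1, e1, _) in zip(gamete, gamete[1:]):
            assert e0 == s1


class TestPedigree:
    def test_parent_must_precede_child(self):
        with pytest.raises(ValueError, match="not defined before use"):
            rk.PedigreeSpec(
                founders={"a": "A"}, matings=(("a", "ghost", "c"),), focal_id="c"
            )

    def test_focal_must_exist(self):
        with pytest.raises(ValueError, match="focal"):
            rk.PedigreeSpec(founders={"a": "A"}, matings=(), focal_id="zz")

    def test_unrelated_founders_single_mating_no_autozygosity(self):
        spec = rk.PopulationPanelSpec(scaffold_lengths={"s1": 10_000_000}, seed=0)
        pool = rk.simulate_panels(spec)
        ped = rk.PedigreeSpec(
            founders={"p": "A", "q": "A"}, matings=(("p", "q", "kid"),), focal_id="kid"
        )
        _, truth = rk.simulate_pedigree(ped, pool, seed=1, render=False)
        assert truth.autozygous == []

    def test_cross_population_parents_give_fully_mixed_ancestry(self):
        spec = rk.PopulationPanelSpec(scaffold_lengths={"s1": 10_000_000}, seed=0)
        pool = rk.simulate_panels(spec)
        ped = rk.PedigreeSpec(
            founders={"p": "A", "q": "B"}, matings=(("p", "q", "kid"),), focal_id="kid"
        )
        _, truth = rk.simulate_pedigree(ped, pool, seed=1, render=False)
        dip = truth.diploid_ancestry()
        assert all(lab == "MIXED" for _, lab in dip)
        assert sum(iv.length for iv, _ in dip) == 10_000_000

    def test_ancestry_tiles_each_haplotype(self):
        b = rk.scenario(
            "admixed_inbred",
            2,
            sizes={"scaffold_lengths": {"s1": 5_000_000}, "n_panel": 0},
            seed=9,
            render=False,
        )
        for hap in b.truth.ancestry:
            ivs = sorted((iv for iv, _ in hap), key=lambda iv: iv.start)
            assert ivs[0].start == 0 and ivs[-1].end == 5_000_000
            for a, c in zip(ivs, ivs[1:]):
                assert a.end == c.start

    def test_focal_het_sites_never_inside_autozygous_truth(self, isolated_bundle):
        b = isolated_bundle
        for iv in b.truth.autozygous:
            seg = b.focal.scaffolds[iv.scaffold][iv.start : iv.end]
            assert not (set(seg) & set("RYSWKM"))


class TestTractLengthFormula:
    def test_selfing_chain_mean_tract_length(self):
        # single-generation selfing loop: ancestor 1 generation back
        mb = rk.collect_truth_tract_lengths(
            g=1, n_tracts=400, scaffold_lengths={"s0": 2_000_000_000}, seed=3
        ) / 1e6
        expect = rk.expected_tract_length_mb(1)  # 45.45 Mb
        se = mb.std(ddof=1) / np.sqrt(len(mb))
        assert abs(mb.mean() - expect) < 3 * se

    def test_deep_loop_mean_tract_length(self):
        # a moderately large founder pool keeps adjacent-tract merging
        # (which inflates the renewal mean by ~1/(2K)) below tolerance
        mb = rk.collect_truth_tract_lengths(g=8, n_tracts=500, n_founders=8, seed=4) / 1e6
        expect = rk.expected_tract_length_mb(8)  # 5.68 Mb
        se = mb.std(ddof=1) / np.sqrt(len(mb))
        assert abs(mb.mean() - expect) < 3 * se


class TestScenarios:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            rk.scenario("mystery", 3)

    def test_outputs_are_deterministic_given_seed(self, tmp_path):
        sizes = {"scaffold_lengths": {"s1": 2_000_000}, "n_panel": 1}
        for d in ("a", "b"):
            rk.scenario("isolated_inbred", 2, sizes=sizes, seed=42, outdir=tmp_path / d)
        for fname in ("focal.fasta", "panelA_0.fasta", "truth_roh.bed", "truth_ancestry_hap0.bed"):
            assert (tmp_path / "a" / fname).read_bytes() == (tmp_path / "b" / fname).read_bytes()

    def test_autozygous_truth_lies_in_single_ancestry_regions(self):
        b = rk.scenario(
            "admixed_inbred",
            2,
            sizes={"scaffold_lengths": {f"s{i}": 20_000_000 for i in range(3)}, "n_panel": 0},
            seed=17,
            render=False,
        )
        dip = b.truth.diploid_ancestry()
        for iv in b.truth.autozygous:
            covering = [
                lab
                for seg, lab in dip
                if seg.scaffold == iv.scaffold and seg.start <= iv.start and seg.end >= iv.end
            ]
            assert covering and covering[0] in ("A", "B")
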