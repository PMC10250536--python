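"""Recurrence and functional-impact tests, Fisher combination, BH, cohort runs."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from driverscan import (
    GeneModel,
    GenomeSequence,
    Interval,
    MutationRecord,
    RegionSet,
    ScoreTrack,
    SimulationConfig,
    adjust_fdr,
    build_context_index,
    fisher_combine,
    functional_impact_test,
    recurrence_test,
    run_cohort,
)
from driverscan.engine import GeneResult, empirical_pvalue, simulate_repositioned


def make_gene(exonic, background, chrom="t"):
    span = Interval(
        chrom,
        min(i.start for i in exonic.intervals()),
        max(i.end for i in exonic.intervals()),
    )
    return GeneModel("G", "G", chrom, "+", span, exonic, background)


def poly_a_gene(split=5, length=12):
    exonic = RegionSet.single("t", 0, split)
    background = RegionSet.single("t", split, length)
    return make_gene(exonic, background)


def mut(pos, context="AAA", sample="s0", chrom="t"):
    return MutationRecord(chrom, pos, "A", "G", sample, context=context)


class TestEmpiricalPvalue:
    def test_modes(self):
        assert empirical_pvalue(0, 100, "add_one") == pytest.approx(1 / 101)
        assert empirical_pvalue(100, 100, "add_one") == 1.0
        assert empirical_pvalue(0, 100, "literal") == pytest.approx(1 / 100)
        assert empirical_pvalue(5, 100, "literal") == pytest.approx(0.05)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_simulations=0)
        with pytest.raises(ValueError):
            SimulationConfig(pseudocount_mode="bogus")


class TestRecurrence:
    def test_no_mutations_skipped(self, poly_a_genome):
        gene = poly_a_gene()
        idx = build_context_index(poly_a_genome, gene.joint)
        obs, nbg, p, flags = recurrence_test(gene, [], idx, SimulationConfig(100, seed=0))
        assert (obs, nbg, p) == (0, 0, 1.0) and "no_mutations" in flags

    def test_degenerate_all_exonic_contexts(self):
        # background has no matching context: every simulation lands exonically
        genome = GenomeSequence({"t": "AAAAACCCCCC"})
        gene = make_gene(RegionSet.single("t", 0, 5), RegionSet.single("t", 5, 11))
        idx = build_context_index(genome, gene.joint)
        muts = [mut(2, "AAA")]
        _, _, p, _ = recurrence_test(gene, muts, idx, SimulationConfig(500, seed=1))
        assert p == 1.0

    def test_unmappable_context_stays_at_origin(self, poly_a_genome):
        gene = poly_a_gene()
        idx = build_context_index(poly_a_genome, gene.joint)
        muts = [mut(1, "NNN")]  # context with no candidates
        obs, _, p, flags = recurrence_test(gene, muts, idx, SimulationConfig(200, seed=1))
        assert obs == 1 and p == 1.0  # fixed exonic contribution in every sim
        assert "unmappable_context" in flags

    def test_matches_binomial_oracle(self, poly_a_genome):
        """Empirical p approaches P(Binomial(3, k_ex/k_tot) >= 3) from enumeration."""
        gene = poly_a_gene()
        idx = build_context_index(poly_a_genome, gene.joint)
        candidates = idx.positions("AAA")
        k_ex = int(gene.exonic.contains_many("t", candidates).sum())
        exact = float(sps.binom.sf(2, 3, k_ex / len(candidates)))
        muts = [mut(p, "AAA", f"s{p}") for p in (1, 2, 3)]
        _, _, p_re, _ = recurrence_test(
            gene, muts, idx, SimulationConfig(40_000, seed=11)
        )
        assert p_re == pytest.approx(exact, abs=0.01)

    def test_binomial_path_agrees_with_positional_path(self, poly_a_genome):
        """The per-context Binomial draw and explicit repositioning give the
        same exceedance probability."""
        gene = poly_a_gene()
        idx = build_context_index(poly_a_genome, gene.joint)
        muts = [mut(p, "AAA", f"s{p}") for p in (1, 2, 3)]
        rng = np.random.default_rng(5)
        landed = simulate_repositioned(muts, idx, rng, 40_000)
        counts = gene.exonic.contains_many("t", landed.ravel()).reshape(landed.shape).sum(axis=0)
        p_positional = empirical_pvalue(int((counts >= 3).sum()), 40_000)
        _, _, p_binomial, _ = recurrence_test(
            gene, muts, idx, SimulationConfig(40_000, seed=6)
        )
        assert p_positional == pytest.approx(p_binomial, abs=0.01)

    def test_repositioning_conserves_region_and_context(self, toy_genome):
        """Instrumented run: every landing lies in the region and keeps the
        mutation's trinucleotide context."""
        from driverscan import trinucleotide_context

        region = RegionSet([Interval("chr1", 2, 18), Interval("chr1", 22, 38)])
        idx = build_context_index(toy_genome, region)
        muts = [
            MutationRecord("chr1", p, toy_genome.fetch("chr1", p, p + 1), "A", "s",
                           context=trinucleotide_context(toy_genome, "chr1", p))
            for p in (3, 7, 25, 30)
        ]
        landed = simulate_repositioned(muts, idx, np.random.default_rng(0), 200)
        ordered = sorted(muts, key=MutationRecord.sort_key)
        assert landed.shape == (4, 200)
        for row, m in zip(landed, ordered):
            assert region.contains_many("chr1", row).all()
            for pos in np.unique(row):
                assert trinucleotide_context(toy_genome, "chr1", int(pos)) == m.context


class TestFunctionalImpact:
    def _setup(self, scores, n_positions=3):
        genome = GenomeSequence({"t": "A" * 12})
        gene = poly_a_gene(split=n_positions + 2)
        idx = build_context_index(genome, RegionSet.single("t", 1, 1 + n_positions))
        track = ScoreTrack.from_pairs(
            [("t", 1 + i, s) for i, s in enumerate(scores)]
        )
        return gene, idx, track

    def test_constant_track_gives_p_one(self):
        gene, idx, track = self._setup([4.2, 4.2, 4.2])
        muts = [mut(2), mut(3, sample="s1")]
        mean, p, _ = functional_impact_test(gene, muts, idx, track, SimulationConfig(300, seed=2))
        assert mean == 4.2 and p == 1.0

    def test_two_outcome_enumeration(self):
        gene, idx, track = self._setup([1.0, 9.0], n_positions=2)
        mean, p, _ = functional_impact_test(
            gene, [mut(2)], idx, track, SimulationConfig(20_000, seed=3)
        )
        assert mean == 9.0
        assert p == pytest.approx(0.5, abs=0.02)

    def test_no_exonic_mutations(self):
        gene, idx, track = self._setup([1.0])
        mean, p, flags = functional_impact_test(gene, [], idx, track, SimulationConfig(10, seed=0))
        assert math.isnan(mean) and p == 1.0 and "no_exonic_mutations" in flags

    def test_all_unscored_flagged(self):
        gene, idx, _ = self._setup([1.0, 2.0])
        empty = ScoreTrack.from_pairs([])
        mean, p, flags = functional_impact_test(
            gene, [mut(2)], idx, empty, SimulationConfig(10, seed=0)
        )
        assert math.isnan(mean) and p == 1.0 and "no_scored_mutations" in flags

    def test_unscored_landings_excluded_from_mean(self):
        # positions 1..3 share context; only two are scored
        gene, idx, _ = self._setup([0.0, 6.0, 9.0])
        track = ScoreTrack.from_pairs([("t", 2, 6.0), ("t", 3, 9.0)])
        mean, p, flags = functional_impact_test(
            gene, [mut(3)], idx, track, SimulationConfig(30_000, seed=4)
        )
        # conditional on a scored landing, P(mean >= 9) = 1/2; unscored sims
        # never count as extreme, so p = (1/3)*0 + (2/3)*(1/2) = 1/3
        assert mean == 9.0
        assert p == pytest.approx(1 / 3, abs=0.02)


class TestFisherCombine:
    def test_neutral_inputs(self):
        T, p = fisher_combine(1.0, 1.0)
        assert T == 0.0 and p == 1.0

    def test_closed_form_df4(self):
        T, p = fisher_combine(math.exp(-2), math.exp(-2))
        assert T == pytest.approx(8.0, rel=1e-12)
        assert p == pytest.approx(5 * math.exp(-4), rel=1e-12)
        assert p == pytest.approx((1 + T / 2) * math.exp(-T / 2), rel=1e-12)

    def test_monotone_in_each_argument(self):
        assert fisher_combine(0.01, 0.5)[1] < fisher_combine(0.05, 0.5)[1]
        assert fisher_combine(0.5, 0.01)[1] < fisher_combine(0.5, 0.05)[1]

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            fisher_combine(bad, 0.5)


class TestAdjustFdr:
    def _results(self, ps, flags=None):
        out = []
        for i, p in enumerate(ps):
            r = GeneResult(gene_id=f"g{i}", p_combined=p)
            if flags and i in flags:
                r.flags.add("no_mutations")
            out.append(r)
        return out

    def test_hand_computed_bh(self):
        rs = adjust_fdr(self._results([0.01, 0.02, 0.03]))
        assert [r.q_value for r in rs] == pytest.approx([0.03, 0.03, 0.03])

    def test_single_gene(self):
        rs = adjust_fdr(self._results([0.2]))
        assert rs[0].q_value == pytest.approx(0.2)

    def test_all_ones(self):
        rs = adjust_fdr(self._results([1.0, 1.0, 1.0]))
        assert all(r.q_value == 1.0 for r in rs)

    def test_skipped_genes_excluded_from_m(self):
        rs = adjust_fdr(self._results([0.01, 0.5, 0.5], flags={1, 2}))
        # only one tested gene: q equals its p
        assert rs[0].q_value == pytest.approx(0.01)
        assert rs[1].q_value == 1.0 and rs[2].q_value == 1.0


class TestRunCohort:
    def _toy(self, seed=0):
        from driverscan import SyntheticSpec, generate_cohort

        spec = SyntheticSpec(
            genome_length=100_000, n_genes=20, n_mutations=1500, seed=seed
        )
        return generate_cohort(spec)

    def test_zero_mutation_cohort(self):
        ds = self._toy()
        results, manifest = run_cohort(
            ds.genes, [], ds.genome, scores=ds.scores, all_exons=ds.all_exons,
            cfg=SimulationConfig(50, seed=1),
        )
        assert all("no_mutations" in r.flags for r in results)
        assert all(r.q_value == 1.0 for r in results)
        assert manifest["n_tested"] == 0

    def test_deterministic_and_order_invariant(self):
        ds = self._toy(seed=3)
        cfg = SimulationConfig(200, seed=9)
        kw = dict(scores=ds.scores, all_exons=ds.all_exons, cfg=cfg)
        r1, _ = run_cohort(ds.genes, ds.mutations, ds.genome, **kw)
        r2, _ = run_cohort(ds.genes, ds.mutations, ds.genome, **kw)
        shuffled = list(ds.mutations)
        np.random.default_rng(0).shuffle(shuffled)
        r3, _ = run_cohort(ds.genes[::-1], shuffled, ds.genome, **kw)
        key = lambda rs: sorted((r.gene_id, r.p_re, r.p_fi, r.q_value) for r in rs)
        assert key(r1) == key(r2) == key(r3)

    def test_mask_excludes_mutations_and_candidates(self):
        ds = self._toy(seed=5)
        gene = ds.genes[0]
        mask = gene.exonic  # mask out the first gene's exons entirely
        results, _ = run_cohort(
            ds.genes[:3], ds.mutations, ds.genome, scores=ds.scores,
            all_exons=ds.all_exons, mask=mask, cfg=SimulationConfig(50, seed=1),
        )
        first = next(r for r in results if r.gene_id == gene.gene_id)
        assert first.n_exonic_obs == 0
        assert "empty_exonic" in first.flags or first.p_re == 1.0

    def test_without_scores_fi_is_one(self):
        ds = self._toy(seed=6)
        results, _ = run_cohort(
            ds.genes[:5], ds.mutations, ds.genome, all_exons=ds.all_exons,
            cfg=SimulationConfig(100, seed=2),
        )
        tested = [r for r in results if r.tested]
        assert tested and all(r.p_fi == 1.0 for r in tested)
        assert all("no_score_track" in r.flags for r in tested)
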