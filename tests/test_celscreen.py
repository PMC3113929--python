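"""Pooling, heteroduplex cleavage, the sum rule, and deconvolution."""

import numpy as np
import pytest

from polytill.celscreen import (CleavageSignal, DetectionCall, InconsistencyError,
                                cleavage_signals, deconvolute, detect,
                                heteroduplex_sites, make_pools, run_screen)
from polytill.popsim import (Individual, MutagenesisParams, Population, Variant,
                             simulate_m2)


def _population(genes, genotypes, groups=None):
    inds = [Individual(id=f"I{i+1}", genotype=g,
                       group=(groups[i] if groups else "EMS"))
            for i, g in enumerate(genotypes)]
    return Population(individuals=inds, params=None, loci=list(genes.values()))


def _planted(gene_id, pos, ref, alt, zyg="het"):
    return {(gene_id, pos): Variant(ref, alt, "substitution", zyg)}


@pytest.fixture()
def h2(fx):
    gid = "h2-1"
    return gid, fx.genes[gid], fx.schemes[gid], fx.amplicons[gid]


class TestPools:
    def test_eight_individuals_make_two_full_pools(self, fx):
        pop = _population(fx.genes, [{} for _ in range(8)])
        pools = make_pools(pop, 4)
        assert [p.well_id for p in pools] == ["1-A1", "1-A2"]
        assert pools[0].member_ids == ("I1", "I2", "I3", "I4")

    def test_remainder_goes_into_a_smaller_last_pool(self, fx):
        pop = _population(fx.genes, [{} for _ in range(5)])
        pools = make_pools(pop, 4)
        assert [len(p.member_ids) for p in pools] == [4, 1]

    def test_pool_size_one_is_individual_screening(self, fx):
        pop = _population(fx.genes, [{} for _ in range(3)])
        assert all(len(p.member_ids) == 1 for p in make_pools(pop, 1))

    def test_wells_roll_over_plates(self, fx):
        pop = _population(fx.genes, [{} for _ in range(97 * 4)])
        pools = make_pools(pop, 4)
        assert pools[95].well_id == "1-H12"
        assert pools[96].well_id == "2-A1"


class TestHeteroduplex:
    def test_all_wild_type_pool_is_silent(self, h2):
        gid, gm, _, amp = h2
        members = [Individual(id=f"I{i}") for i in range(4)]
        assert heteroduplex_sites(members, gid, amp) == []

    def test_one_het_member_marks_its_site(self, h2):
        gid, gm, _, amp = h2
        site = amp.start + 500
        members = [Individual(id="I1", genotype=_planted(gid, site, "G", "A"))]
        members += [Individual(id=f"I{i}") for i in range(2, 5)]
        assert heteroduplex_sites(members, gid, amp) == [site]

    def test_homozygote_alone_is_invisible_until_mixed_with_wild_type(self, h2):
        gid, gm, _, amp = h2
        site = amp.start + 500
        hom = Individual(id="I1", genotype=_planted(gid, site, "G", "A", "hom"))
        assert heteroduplex_sites([hom], gid, amp) == []
        assert heteroduplex_sites([hom], gid, amp, include_wt=True) == [site]

    def test_pooled_homozygote_is_visible_via_wild_type_poolmates(self, h2):
        gid, gm, _, amp = h2
        site = amp.start + 500
        members = [Individual(id="I1", genotype=_planted(gid, site, "G", "A", "hom")),
                   Individual(id="I2")]
        assert heteroduplex_sites(members, gid, amp) == [site]


class TestSignalsAndDetection:
    def test_fragments_sum_to_the_amplicon_length(self, h2):
        _, _, _, amp = h2
        site = amp.start + 449  # offset 450 on a 1278-bp product
        s700, s800 = cleavage_signals(site, amp)
        assert (s700.size, s800.size) == (450, 828)
        assert s700.size + s800.size == amp.length

    def test_boundary_offset_one(self, h2):
        _, _, _, amp = h2
        s700, s800 = cleavage_signals(amp.start, amp)
        assert (s700.size, s800.size) == (1, amp.length - 1)

    def test_site_outside_amplicon_raises(self, h2):
        _, _, _, amp = h2
        with pytest.raises(ValueError):
            cleavage_signals(amp.start - 1, amp)

    def test_sum_rule_calls_and_edge_exclusion(self):
        L = 1278
        calls = detect([CleavageSignal(700, 450), CleavageSignal(800, 828)], L)
        assert [c.cut_position for c in calls] == [450]
        assert detect([CleavageSignal(700, 50), CleavageSignal(800, 1228)], L) == []
        assert detect([CleavageSignal(700, 450), CleavageSignal(800, 700)], L) == []

    def test_symmetric_positions_warn_about_comigration(self):
        L = 1000
        signals = [CleavageSignal(700, 300), CleavageSignal(800, 700),
                   CleavageSignal(700, 700), CleavageSignal(800, 300)]
        with pytest.warns(UserWarning, match="co-migrating"):
            calls = detect(signals, L)
        assert sorted(c.cut_position for c in calls) == [300, 700]


class TestDeconvolution:
    def _call(self, amp, site):
        return DetectionCall(amplicon_id=amp.gene_id, cut_position=site - amp.start + 1,
                             source_id="1-A1")

    def test_het_carrier_is_identified(self, h2):
        gid, _, _, amp = h2
        site = amp.start + 400
        members = [Individual(id="I1"), Individual(id="I2"),
                   Individual(id="I3", genotype=_planted(gid, site, "G", "A")),
                   Individual(id="I4")]
        assert deconvolute(self._call(amp, site), members, gid, amp) == [("I3", "het")]

    def test_hom_carrier_is_positive_only_when_mixed(self, h2):
        gid, _, _, amp = h2
        site = amp.start + 400
        members = [Individual(id="I1"),
                   Individual(id="I2", genotype=_planted(gid, site, "G", "A", "hom")),
                   Individual(id="I3"), Individual(id="I4")]
        assert deconvolute(self._call(amp, site), members, gid, amp) == [("I2", "hom")]

    def test_spurious_call_raises_inconsistency(self, h2):
        gid, _, _, amp = h2
        members = [Individual(id=f"I{i}") for i in range(4)]
        with pytest.raises(InconsistencyError):
            deconvolute(self._call(amp, amp.start + 400), members, gid, amp)


class TestRunScreen:
    def test_clean_population_yields_no_records(self, fx):
        pop = _population(fx.genes, [{} for _ in range(8)])
        records, tally = run_screen(pop, fx.genes, fx.schemes)
        assert records.empty
        assert tally.n_mutations() == 0
        assert not tally.density().defined

    def test_single_planted_het_is_recovered_exactly(self, fx):
        gid = "h2-2"
        amp = fx.amplicons[gid]
        site = amp.start + 600
        genotypes = [{} for _ in range(7)] + [_planted(gid, site, "G", "A")]
        pop = _population(fx.genes, genotypes)
        records, _ = run_screen(pop, fx.genes, fx.schemes)
        assert len(records) == 1
        row = records.iloc[0]
        assert (row.individual, row.gene_id, row.locus_pos, row.zygosity) == \
            ("I8", gid, site, "het")

    def test_mutation_in_the_gel_edge_is_missed(self, fx):
        gid = "h2-1"
        amp = fx.amplicons[gid]
        site = amp.start + 39  # 40 bp from the labeled end
        pop = _population(fx.genes, [_planted(gid, site, "G", "A")])
        records, _ = run_screen(pop, fx.genes, fx.schemes)
        assert records.empty

    def test_completeness_on_random_populations(self, fx):
        """Every in-window variant carried by a pool member is called with
        the right zygosity, and nothing else is called."""
        pop = simulate_m2(fx.gene_list(), 200,
                          MutagenesisParams(density=5e-5, rng_seed=17))
        records, _ = run_screen(pop, fx.genes, fx.schemes)
        got = {(r.individual, r.gene_id, r.locus_pos): r.zygosity
               for r in records.itertuples()}
        expected = {}
        for ind in pop.individuals:
            for (gid, pos), var in ind.genotype.items():
                amp = fx.amplicons[gid]
                off = pos - amp.start + 1
                if 100 < off < amp.length - 100:
                    expected[(ind.id, gid, pos)] = var.zygosity
        assert got == expected
        assert len(expected) > 30  # the check is not vacuous

    def test_edge_loss_matches_the_uniform_expectation(self, fx):
        """Detected fraction of uniformly placed variants ~ (L-200)/L."""
        gid = "h2-1"
        gm, amp = fx.genes[gid], fx.amplicons[gid]
        rng = np.random.default_rng(23)
        n = 2000
        genotypes = []
        for _ in range(n):
            off = int(rng.integers(1, amp.length + 1))
            pos = amp.start + off - 1
            ref = gm.locus_seq[pos - 1]
            alt = "A" if ref != "A" else "G"
            genotypes.append(_planted(gid, pos, ref, alt))
        pop = _population({gid: gm}, genotypes)
        records, _ = run_screen(pop, {gid: gm}, {gid: fx.schemes[gid]})
        p = (amp.length - 200) / amp.length
        mu, sd = n * p, np.sqrt(n * p * (1 - p))
        assert abs(len(records) - mu) <= 3 * sd

    def test_grouped_tally_feeds_the_frequency_report(self, fx):
        gid = "h2-1"
        amp = fx.amplicons[gid]
        genotypes = [_planted(gid, amp.start + 500, "G", "A"), {}, {}, {}]
        pop = _population(fx.genes, genotypes, groups=["g1", "g1", "g2", "g2"])
        records, tally = run_screen(pop, fx.genes, fx.schemes)
        assert tally.group_labels() == ["g1", "g2"]
        assert tally.n_mutations(["g1"]) == 1
        assert tally.n_mutations(["g2"]) == 0
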