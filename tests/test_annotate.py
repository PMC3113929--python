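"""Codon bookkeeping, effect classification, epitopes, and the EMS spectrum."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polytill import annotate
from polytill.annotate import (EpitopeMap, Mutation, ReferenceMismatchError,
                               classify, codon_index, epitope_overlap,
                               mutation_from_notation, mutation_to_notation,
                               spectrum_summary)
from polytill.genemodels import GeneModel, translate
from polytill.popsim import random_gene_model

_BASES = "ACGT"
_SENSE = [a + b + c for a in _BASES for b in _BASES for c in _BASES
          if a + b + c not in ("TAA", "TAG", "TGA")]


class TestCodonIndex:
    @pytest.mark.parametrize("cds_pos,codon,offset", [
        (145, 49, 1), (164, 55, 2), (185, 62, 2), (208, 70, 1),
        (304, 102, 1), (448, 150, 1), (761, 254, 2), (3, 1, 3), (1, 1, 1),
    ])
    def test_benchmark_residue_numbers(self, cds_pos, codon, offset):
        assert codon_index(cds_pos) == (codon, offset)

    def test_rejects_nonpositive_positions(self):
        with pytest.raises(ValueError):
            codon_index(0)


class TestClassify:
    def test_every_consistent_table_row_reproduces_its_effect(self, fx):
        df = fx.mutations[~fx.mutations["anomalous"]]
        for row in df.itertuples():
            m = Mutation(row.gene_id, row.anchored_pos, row.ref, row.alt, row.kind)
            eff = classify(m, fx.genes[row.gene_id])
            assert eff.effect_class == row.table_class, row
            if row.aa_change and row.kind == "substitution":
                assert f"{eff.wt_aa}{eff.codon_index}{eff.mut_aa}" == row.aa_change

    def test_start_loss_records_absence_of_inframe_rescue_atg(self, fx):
        eff = classify(Mutation("h2-2", 3, "G", "A"), fx.genes["h2-2"])
        assert eff.effect_class == "start_loss"
        assert "no in-frame downstream ATG" in eff.notes

    def test_nonsense_truncation_counts_residues_before_the_stop(self, fx):
        eff = classify(Mutation("h1-2", 304, "C", "T"), fx.genes["h1-2"])
        assert eff.effect_class == "nonsense"
        assert eff.codon_index == 102
        assert eff.truncated_length == 101

    def test_frameshift_truncation_matches_direct_retranslation(self, fx):
        gm = fx.genes["fad2b"]
        eff = classify(Mutation("fad2b", 442, "A", "A", "insertion"), gm)
        assert eff.effect_class == "frameshift"
        cds = gm.cds_seq()
        shifted = cds[:442] + "A" + cds[442:]
        aa = translate(shifted[: 3 * (len(shifted) // 3)], to_first_stop=True)
        assert eff.truncated_length == len(aa) - 1

    def test_upstream_and_intron_placement(self, fx):
        eff = classify(Mutation("h2-2", -315, "G", "A"), fx.genes["h2-2"])
        assert eff.effect_class == "upstream"
        gm = fx.genes["h1-1"]
        pos = 760 - gm.upstream_len  # inside intron 1 (locus 751..950)
        ref = gm.base_at(760)
        alt = "A" if ref != "A" else "G"
        eff = classify(Mutation("h1-1", pos, ref, alt), gm)
        assert eff.effect_class == "intron"

    def test_reference_mismatch_is_an_error(self, fx):
        wrong_ref = "A" if fx.genes["h2-1"].cds_seq()[144] != "A" else "G"
        with pytest.raises(ReferenceMismatchError):
            classify(Mutation("h2-1", 145, wrong_ref, "T"), fx.genes["h2-1"])

    def test_no_substitution_at_codon_offset_two_is_ever_silent(self):
        """Wobble only exists at the third position: middle-base changes
        always alter the residue (or create a stop)."""
        for codon in _SENSE:
            gm = GeneModel("t", "A", "ATG" + codon + "TAA", 0, [(1, 9)])
            for alt in _BASES:
                if alt == codon[1]:
                    continue
                eff = classify(Mutation("t", 5, codon[1], alt), gm)
                assert eff.effect_class != "silent", (codon, alt)

    @settings(max_examples=120, derandomize=True)
    @given(seed=st.integers(0, 5), cds_pos=st.integers(1, 360),
           alt_i=st.integers(0, 3))
    def test_matches_the_full_cds_diff_oracle(self, seed, cds_pos, alt_i):
        """classify agrees with brute force: translate the whole wild-type
        and mutant CDS and diff the proteins."""
        gm = random_gene_model("r", n_codons=120, upstream_len=10,
                               downstream_len=10, seed=seed)
        cds = gm.cds_seq()
        ref, alt = cds[cds_pos - 1], _BASES[alt_i]
        if alt == ref:
            return
        eff = classify(Mutation("r", cds_pos, ref, alt), gm)
        mut_cds = cds[: cds_pos - 1] + alt + cds[cds_pos:]
        wt_aa, mut_aa = translate(cds), translate(mut_cds)
        if not mut_cds.startswith("ATG"):
            expected = "start_loss"
        elif "*" in mut_aa[:-1]:
            expected = "nonsense"
        elif wt_aa == mut_aa:
            expected = "silent"
        else:
            expected = "missense"
        assert eff.effect_class == expected


class TestEpitopes:
    def test_residue_333_falls_in_epitope_12(self, fx):
        eff = classify(Mutation("h1-1", 1392, "C", "T"), fx.genes["h1-1"])
        emap = EpitopeMap("h1-1", (("12", (326, 335)),))
        assert epitope_overlap(eff, emap) == ["12"]

    def test_empty_map_and_boundary_inclusion(self):
        gm = random_gene_model(seed=9, upstream_len=0)
        eff = classify(Mutation("toy", 4, gm.cds_seq()[3],
                                "A" if gm.cds_seq()[3] != "A" else "G"), gm)
        assert epitope_overlap(eff, EpitopeMap("toy", ())) == []
        assert epitope_overlap(eff, EpitopeMap("toy", (("e", (2, 2)),))) == ["e"]


class TestSpectrum:
    def test_confirmed_table_splits_22_canonical_5_atypical(self, fx):
        muts = [Mutation(r.gene_id, r.anchored_pos, r.ref, r.alt, r.kind)
                for r in fx.mutations.itertuples()]
        summary = spectrum_summary(muts)
        assert summary["n_canonical"] == 22
        assert summary["n_atypical"] == 5
        assert summary["counts"]["other_substitution"] == 3  # the A->G alleles
        assert summary["counts"]["indel"] == 2  # the A-insertion alleles

    def test_empty_input_gives_zero_tallies(self):
        summary = spectrum_summary([])
        assert summary["n_canonical"] == 0 and summary["atypical"] == []

    def test_single_transversionlike_change_is_atypical(self):
        summary = spectrum_summary([Mutation("g", 10, "A", "G")])
        assert summary["n_atypical"] == 1


class TestNotationIO:
    @pytest.mark.parametrize("notation,kind", [
        ("C145>T", "substitution"), ("A442insA", "insertion"),
        ("G-315>A", "substitution"), ("ACG-12del", "deletion"),
    ])
    def test_notation_round_trip(self, notation, kind):
        m = mutation_from_notation("g", notation)
        assert m.kind == kind
        assert mutation_to_notation(m) == notation

    def test_effect_table_is_written_with_annotations(self, tmp_path, fx):
        muts = [Mutation("h1-2", 304, "C", "T"),
                Mutation("fad2b", 442, "A", "A", "insertion")]
        df = annotate.write_effect_table(muts, fx.genes, tmp_path / "eff.tsv")
        assert list(df["effect"]) == ["nonsense", "frameshift"]
        assert (tmp_path / "eff.tsv").exists()
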