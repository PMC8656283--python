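import numpy as np
import pytest

from conftest import gm_pos, gp_pos
from uvsomatic.io_formats import SomaticCall, revcomp
from uvsomatic.mutation_classes import (
    CONTEXT_LABELS,
    MutationRecord,
    annotate_records,
    context_index_of,
    hgvs_label,
    merge_adjacent_snvs,
    trinucleotide_context,
)


def call(pos, ref, alt, sample="s1", chrom="chr1"):
    return SomaticCall(sample, chrom, pos, ref, alt, 10, 50, 0, 50)


class TestMergeAdjacentSnvs:
    def test_adjacent_ct_pair_becomes_cc_tt_dbs(self):
        records = merge_adjacent_snvs([call(100, "C", "T"), call(101, "C", "T")])
        (rec,) = records
        assert rec.mtype == "DBS"
        assert (rec.start, rec.end, rec.ref, rec.alt) == (100, 101, "CC", "TT")
        assert rec.is_cc_tt

    def test_gg_aa_counts_as_cc_tt_on_the_other_strand(self):
        (rec,) = merge_adjacent_snvs([call(100, "G", "A"), call(101, "G", "A")])
        assert rec.is_cc_tt

    def test_gap_of_one_stays_two_snvs(self):
        records = merge_adjacent_snvs([call(100, "C", "T"), call(102, "C", "T")])
        assert [r.mtype for r in records] == ["SNV", "SNV"]

    def test_merging_is_per_sample(self):
        records = merge_adjacent_snvs(
            [call(100, "C", "T", "A"), call(101, "C", "T", "B")]
        )
        assert [r.mtype for r in sorted(records, key=lambda r: r.sample_id)] \
            == ["SNV", "SNV"]

    def test_run_of_three_becomes_delins_outside_dbs(self):
        (rec,) = merge_adjacent_snvs(
            [call(100, "C", "T"), call(101, "C", "T"), call(102, "C", "A")]
        )
        assert rec.mtype == "INDEL"
        assert (rec.ref, rec.alt) == ("CCC", "TTA")
        assert rec.merged_from == 3

    def test_duplicate_call_raises(self):
        with pytest.raises(ValueError, match="duplicate"):
            merge_adjacent_snvs([call(100, "C", "T"), call(100, "C", "T")])

    def test_indel_passthrough_and_long_flag(self):
        records = merge_adjacent_snvs(
            [call(100, "CAAAA", "C"), call(200, "CA", "C")]
        )
        by_pos = {r.start: r for r in records}
        assert by_pos[100].mtype == "INDEL" and by_pos[100].long_indel
        assert by_pos[200].mtype == "INDEL" and not by_pos[200].long_indel

    def test_base_conservation(self, rng):
        """#SNV + 2*#DBS + merged-run bases equals the input SNV count."""
        positions = sorted(rng.choice(np.arange(1, 400), 80, replace=False))
        calls = [call(int(p), "C", "T") for p in positions]
        records = merge_adjacent_snvs(calls)
        spanned = sum(
            1 if r.mtype == "SNV" else len(r.ref) for r in records
        )
        assert spanned == len(calls)


class TestTrinucleotideContext:
    def _ref(self, seq):
        from uvsomatic.io_formats import Reference

        return Reference({"chr1": seq})

    def test_pyrimidine_reference_unchanged(self):
        ref = self._ref("AACGT")
        rec = MutationRecord("s", "chr1", 3, 3, "C", "T", "SNV")
        assert CONTEXT_LABELS[trinucleotide_context(rec, ref)] == "A[C>T]G"

    def test_purine_reference_is_reverse_complemented(self):
        # C[G>A]C -> G[C>T]G after pyrimidine normalization
        ref = self._ref("ACGCT")
        rec = MutationRecord("s", "chr1", 3, 3, "G", "A", "SNV")
        assert CONTEXT_LABELS[trinucleotide_context(rec, ref)] == "G[C>T]G"

    def test_dbs_record_rejected(self):
        ref = self._ref("AACCGG")
        rec = MutationRecord("s", "chr1", 3, 4, "CC", "TT", "DBS")
        with pytest.raises(ValueError, match="SNV"):
            trinucleotide_context(rec, ref)

    def test_contig_edge_is_an_error(self):
        ref = self._ref("CGT")
        rec = MutationRecord("s", "chr1", 1, 1, "C", "T", "SNV")
        with pytest.raises(ValueError, match="flanking"):
            trinucleotide_context(rec, ref)

    def test_index_is_bijective_with_labels(self):
        seen = set()
        for five in "ACGT":
            for ref_b, alts in (("C", "AGT"), ("T", "ACG")):
                for alt in alts:
                    for three in "ACGT":
                        k = context_index_of(five, ref_b, alt, three)
                        assert CONTEXT_LABELS[k] == f"{five}[{ref_b}>{alt}]{three}"
                        seen.add(k)
        assert seen == set(range(96))

    def test_strand_symmetry(self):
        for five in "ACGT":
            for three in "ACGT":
                k1 = context_index_of(five, "C", "T", three)
                k2 = context_index_of(revcomp(three), "G", "A", revcomp(five))
                assert k1 == k2


class TestHgvsLabels:
    def _record(self, pos, ref, alt, gene, mtype="SNV", end=None):
        rec = MutationRecord("s", "chrT", pos, end or pos + len(ref) - 1,
                             ref, alt, mtype)
        rec.gene_id = gene
        return rec

    def test_utr5_substitution(self, toy):
        _, models = toy
        # 5 nt upstream of the start codon, G>A
        rec = self._record(gp_pos(55), "G", "A", "GP")
        assert hgvs_label(rec, models) == "c.-5G>A"

    def test_utr5_double_substitution_delins(self, toy):
        _, models = toy
        rec = self._record(gp_pos(55), "GG", "AA", "GP", mtype="DBS")
        assert hgvs_label(rec, models) == "c.-5_-4delinsAA"

    def test_utr3_substitutions(self, toy):
        _, models = toy
        rec = self._record(gp_pos(531), "C", "A", "GP")
        assert hgvs_label(rec, models) == "c.*142C>A"
        rec2 = self._record(gp_pos(531), "CC", "TT", "GP", mtype="DBS")
        assert hgvs_label(rec2, models) == "c.*142_*143delinsTT"

    def test_cds_substitution(self, toy):
        _, models = toy
        rec = self._record(gp_pos(60 + 70), "C", "T", "GP")
        assert hgvs_label(rec, models) == "c.71C>T"

    def test_intron_offsets(self, toy):
        _, models = toy
        assert hgvs_label(self._record(gp_pos(150), "G", "A", "GP"),
                          models) == "c.90+1G>A"
        assert hgvs_label(self._record(gp_pos(298), "A", "C", "GP"),
                          models) == "c.91-2A>C"

    @pytest.mark.parametrize("offset,ref,alt,mtype", [
        (55, "G", "A", "SNV"),
        (60 + 70, "C", "T", "SNV"),
        (531, "C", "A", "SNV"),
        (150, "G", "A", "SNV"),
    ])
    def test_minus_strand_twin_yields_identical_label(self, toy, offset, ref,
                                                      alt, mtype):
        _, models = toy
        rec_p = self._record(gp_pos(offset), ref, alt, "GP", mtype)
        rec_m = self._record(gm_pos(offset), revcomp(ref), revcomp(alt), "GM",
                             mtype)
        assert hgvs_label(rec_m, models) == hgvs_label(rec_p, models)

    def test_minus_strand_delins_label(self, toy):
        _, models = toy
        # the -5/-4 GG>AA of the minus gene occupies gm_pos(56)..gm_pos(55)
        rec = MutationRecord("s", "chrT", gm_pos(56), gm_pos(55),
                             "CC", "TT", "DBS")
        rec.gene_id = "GM"
        assert hgvs_label(rec, models) == "c.-5_-4delinsAA"

    def test_unassociated_record_raises(self, toy):
        _, models = toy
        rec = self._record(gp_pos(55), "G", "A", None)
        with pytest.raises(ValueError, match="gene"):
            hgvs_label(rec, models)


class TestAnnotatedCohortContexts:
    def test_pure_uv_cohort_concentrates_in_c_to_t_channels(self):
        """A pure dipyrimidine C>T cohort occupies only C>T context bins."""
        from uvsomatic.signature_fitting import build_96_profile
        from uvsomatic.synthetic_data import SimulationConfig, generate_genome
        from uvsomatic.synthetic_data import simulate_cohort

        config = SimulationConfig(
            seed=5, n_samples=3, n_genes=12, genome_length=140_000,
            lognorm_mu=5.0, n_near_empty=0, n_alkyl_dominant=0,
            uv_weight_mean=0.999, uv_weight_conc=5000.0,
            dbs_fraction=0.0, indel_fraction=0.0,
            planted_hotspots=[], planted_drivers=[],
            n_artifacts_per_reason=0, n_germline_sites=0, n_pon_sites=0,
        )
        reference, models = generate_genome(config)
        calls, _truth = simulate_cohort(config, reference, models)
        records = []
        for sid, rows in calls.items():
            cs = [SomaticCall(sample_id=sid, **row) for row in rows]
            records.extend(merge_adjacent_snvs(cs))
        annotate_records(records, models, reference)
        profile = build_96_profile([r for r in records if r.mtype == "SNV"],
                                   "all")
        ct = profile.counts[32:48].sum()  # the 16 C>T channels
        # the UV signature carries a 5% C>A remainder; C>T must dominate
        assert profile.total > 200
        assert ct / profile.total > 0.9
        # and every C>T context has a pyrimidine 5' neighbour or came from
        # the small C>A remainder
        uv_channels = {
            i for i in range(32, 48)
            if CONTEXT_LABELS[i][0] in "CT"
        }
        in_uv = sum(profile.counts[i] for i in uv_channels)
        assert in_uv / ct > 0.99
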