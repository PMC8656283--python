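import pytest
from Bio.Seq import Seq

from conftest import gm_pos, gp_pos
from uvsomatic.gene_annotation import (
    AnnotationParams,
    RegionClass,
    classify_region,
    coding_effect,
)
from uvsomatic.io_formats import SomaticCall, revcomp


def _call(chrom, pos, ref, alt):
    return SomaticCall("s", chrom, pos, ref, alt, 10, 50, 0, 50)


class TestClassifyRegion:
    @pytest.mark.parametrize("offset,expected", [
        (0, RegionClass.UTR5),          # first UTR5 base
        (59, RegionClass.UTR5),
        (60, RegionClass.CODING),       # ATG
        (149, RegionClass.CODING),      # last base of CDS exon 1
        (150, RegionClass.SPLICE_SITE),  # intron +1
        (151, RegionClass.SPLICE_SITE),  # intron +2
        (152, RegionClass.INTRON),       # intron +3: outside the splice window
        (249, RegionClass.INTRON),
        (298, RegionClass.SPLICE_SITE),  # intron -2
        (300, RegionClass.CODING),       # CDS exon 2 starts
        (390, RegionClass.UTR3),
        (381 + 150, RegionClass.UTR3),   # c.*142, deep into the 3'UTR
    ])
    def test_plus_strand_classes(self, toy, offset, expected):
        reference, models = toy
        cls, gene = classify_region("chrT", gp_pos(offset), models)
        assert cls is expected
        assert gene == "GP"

    @pytest.mark.parametrize("offset", [0, 60, 150, 152, 298, 390, 531])
    def test_minus_strand_mirrors_plus_strand(self, toy, offset):
        reference, models = toy
        cls_p, _ = classify_region("chrT", gp_pos(offset), models)
        cls_m, gene = classify_region("chrT", gm_pos(offset), models)
        assert cls_m is cls_p
        assert gene == "GM"

    def test_intergenic_and_deep_intron(self, toy):
        reference, models = toy
        cls, gene = classify_region("chrT", 50, models)
        assert cls is RegionClass.INTERGENIC and gene is None
        # middle of the 150 nt intron with a 30 nt proximity window
        params = AnnotationParams(intron_prox_window=30)
        cls, _ = classify_region("chrT", gp_pos(225), models, params)
        assert cls is RegionClass.INTRON_DEEP

    def test_intron_window_boundary_is_inclusive(self, toy):
        reference, models = toy
        params = AnnotationParams(intron_prox_window=3)
        assert classify_region("chrT", gp_pos(152), models, params)[0] \
            is RegionClass.INTRON
        assert classify_region("chrT", gp_pos(153), models, params)[0] \
            is RegionClass.INTRON_DEEP

    def test_invalid_position(self, toy):
        _, models = toy
        with pytest.raises(ValueError):
            classify_region("chrT", 0, models)


class TestCodingEffect:
    def test_missense_ser24_phe(self, toy):
        reference, models = toy
        # c.71C>T in codon 24 (TCC -> TTC)
        pos = gp_pos(60 + 70)
        eff = coding_effect(_call("chrT", pos, "C", "T"), models, reference)
        assert eff.kind == "missense"
        assert eff.protein == "Ser24Phe"

    def test_double_substitution_same_codon_is_one_missense(self, toy):
        reference, models = toy
        # c.71_72delinsTT: TCC -> TTT, still Ser24Phe at the protein level
        pos = gp_pos(60 + 70)
        eff = coding_effect(_call("chrT", pos, "CC", "TT"), models, reference)
        assert eff.kind == "missense"
        assert eff.protein == "Ser24Phe"

    def test_stop_gain_is_nonsense(self, toy):
        reference, models = toy
        # codon 2 CAA -> TAA
        pos = gp_pos(60 + 3)
        eff = coding_effect(_call("chrT", pos, "C", "T"), models, reference)
        assert eff.kind == "nonsense"

    def test_synonymous_third_position(self, toy):
        reference, models = toy
        # codon 3 GCT -> GCC (Ala/Ala)
        pos = gp_pos(60 + 8)
        eff = coding_effect(_call("chrT", pos, "T", "C"), models, reference)
        assert eff.kind == "synonymous"

    def test_stop_loss(self, toy):
        reference, models = toy
        # last codon TAA -> CAA
        pos = gp_pos(60 + 90 + 150 + 87)
        eff = coding_effect(_call("chrT", pos, "T", "C"), models, reference)
        assert eff.kind == "stop_loss"

    def test_indel_typing_by_net_length(self, toy):
        reference, models = toy
        pos = gp_pos(60 + 9)
        ref3 = reference.seq("chrT", pos, pos + 2)
        ref4 = reference.seq("chrT", pos, pos + 3)
        one = coding_effect(_call("chrT", pos, ref3[:2], ref3[0]),
                            models, reference)
        assert one.kind == "frameshift"
        three = coding_effect(_call("chrT", pos, ref4, ref4[0]),
                              models, reference)
        assert three.kind == "inframe_indel"

    def test_splice_site_effect(self, toy):
        reference, models = toy
        pos = gp_pos(150)  # intron +1
        eff = coding_effect(_call("chrT", pos, "G", "A"), models, reference)
        assert eff.kind == "splice"

    def test_reference_mismatch_raises(self, toy):
        reference, models = toy
        pos = gp_pos(60)  # 'A' of ATG
        with pytest.raises(ValueError, match="reference mismatch"):
            coding_effect(_call("chrT", pos, "C", "T"), models, reference)

    @pytest.mark.parametrize("offset,ref_alt", [
        (60 + 70, ("C", "T")),   # missense
        (60 + 3, ("C", "T")),    # nonsense
        (60 + 8, ("T", "C")),    # synonymous
    ])
    def test_minus_strand_twin_gives_identical_effect(self, toy, offset, ref_alt):
        reference, models = toy
        ref, alt = ref_alt
        eff_p = coding_effect(_call("chrT", gp_pos(offset), ref, alt),
                              models, reference)
        eff_m = coding_effect(
            _call("chrT", gm_pos(offset), revcomp(ref), revcomp(alt)),
            models, reference)
        assert (eff_m.kind, eff_m.protein) == (eff_p.kind, eff_p.protein)


class TestEffectAgainstFullTranslationOracle:
    """Per-codon effect prediction must agree with brute-force translation
    of the entire mutant CDS, across many random coding SNVs."""

    def test_random_coding_snvs(self, toy, rng):
        reference, models = toy
        for txid in ("TXP", "TXM"):
            tx = models.transcripts[txid]
            cds_positions = [p for s, e in tx.cds for p in range(s, e + 1)]
            for pos in rng.choice(cds_positions, size=120, replace=False):
                pos = int(pos)
                ref = reference.base("chrT", pos)
                alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
                eff = coding_effect(_call("chrT", pos, ref, alt),
                                    models, reference)
                # oracle: splice the full mutant CDS and translate it whole
                idx = tx.cds_index(pos)
                cds_ref = tx.coding_sequence(reference)
                base = alt if tx.strand == "+" else revcomp(alt)
                cds_mut = cds_ref[:idx] + base + cds_ref[idx + 1:]
                p_ref = str(Seq(cds_ref).translate())
                p_mut = str(Seq(cds_mut).translate())
                if p_ref == p_mut:
                    expected = "synonymous"
                else:
                    i = next(k for k, (x, y) in enumerate(zip(p_ref, p_mut))
                             if x != y)
                    stop = p_ref.find("*")
                    if p_mut[i] == "*" and (stop < 0 or i < stop):
                        expected = "nonsense"
                    elif p_ref[i] == "*":
                        expected = "stop_loss"
                    else:
                        expected = "missense"
                assert eff.kind == expected, (txid, pos, ref, alt)


class TestRegionClosureOnSimulatedCohort:
    def test_every_retained_mutation_gets_exactly_one_region(self, small_dataset):
        from uvsomatic.io_formats import SomaticCall
        from uvsomatic.mutation_classes import annotate_records, merge_adjacent_snvs
        from uvsomatic.somatic_filtering import apply_somatic_filters

        models = small_dataset["models"]
        reference = small_dataset["reference"]
        records = []
        for sid, rows in small_dataset["calls"].items():
            truth_artifacts = small_dataset["truth"].artifacts
            bad = {(r.sample, int(r.pos)) for r in truth_artifacts.itertuples()}
            calls = [SomaticCall(sample_id=sid, **row) for row in rows
                     if (sid, row["pos"]) not in bad]
            passed, _ = apply_somatic_filters(calls)
            records.extend(merge_adjacent_snvs(passed))
        annotate_records(records, models, reference)
        assert all(r.region is not None for r in records)
        tally = sum(1 for r in records if r.region is not RegionClass.INTRON_DEEP)
        per_class = {}
        for r in records:
            per_class[r.region] = per_class.get(r.region, 0) + 1
        assert sum(v for k, v in per_class.items()
                   if k is not RegionClass.INTRON_DEEP) == tally
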