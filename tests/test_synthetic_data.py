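import numpy as np
import pytest

from uvsomatic.gene_annotation import classify_region
from uvsomatic.io_formats import (
    Reference,
    SomaticCall,
    load_gene_models,
    load_somatic_calls,
)
from uvsomatic.mutation_classes import context_index_of, merge_adjacent_snvs
from uvsomatic.somatic_filtering import apply_somatic_filters, drop_flagged, flag_sites
from uvsomatic.synthetic_data import (
    SimulationConfig,
    covered_mask,
    generate_genome,
    pair_channels,
    paint_region_classes,
    simulate_cohort,
    simulate_score_track,
)


def tiny_config(**kw):
    defaults = dict(
        seed=3, n_samples=4, n_genes=10, genome_length=120_000,
        lognorm_mu=4.6, n_near_empty=0, n_alkyl_dominant=1,
        planted_hotspots=[], planted_drivers=[],
        n_artifacts_per_reason=4, n_germline_sites=5, n_pon_sites=5,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenerateGenome:
    def test_gene_model_invariants(self):
        reference, models = generate_genome(tiny_config())
        strands = set()
        for gid in models.gene_ids():
            tx = models.canonical(gid)
            strands.add(tx.strand)
            assert len(tx.exons) >= 2
            assert tx.cds_length % 3 == 0
            # CDS and UTRs lie inside exons
            for ivs in (tx.cds, tx.utr5, tx.utr3):
                for s, e in ivs:
                    assert any(es <= s and e <= ee for es, ee in tx.exons)
        assert strands == {"+", "-"}

    def test_seed_determinism_is_byte_identical(self):
        r1, m1 = generate_genome(tiny_config())
        r2, m2 = generate_genome(tiny_config())
        assert r1.seq("chr1", 1, 120_000) == r2.seq("chr1", 1, 120_000)
        assert all(
            m1.transcripts[t].exons == m2.transcripts[t].exons
            for t in m1.transcripts
        )

    def test_too_small_genome_raises(self):
        with pytest.raises(ValueError, match="too small"):
            generate_genome(tiny_config(genome_length=5_000, n_genes=10))

    def test_cds_has_no_internal_stops(self):
        reference, models = generate_genome(tiny_config())
        from Bio.Seq import Seq

        for gid in models.gene_ids():
            tx = models.canonical(gid)
            prot = str(Seq(tx.coding_sequence(reference)).translate())
            assert prot.endswith("*")
            assert "*" not in prot[:-1]


class TestVectorizedChannels:
    def test_pair_channels_matches_scalar_rule(self, rng):
        reference, _ = generate_genome(tiny_config())
        seq = reference.seq("chr1", 1, 5000)
        codes = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in seq])
        positions = rng.integers(2, 4999, size=200)
        alts, chans = pair_channels(codes, positions)
        for i, p in enumerate(positions):
            p = int(p)
            for k in range(3):
                expected = context_index_of(
                    seq[p - 2], seq[p - 1], "ACGT"[alts[i, k]], seq[p]
                )
                assert chans[i, k] == expected

    def test_painted_classes_match_classify_region(self, rng):
        config = tiny_config()
        reference, models = generate_genome(config)
        region_arr, _gene_arr, _ids = paint_region_classes(config, models)
        from uvsomatic.synthetic_data import _CODE_TO_REGION

        params = config.annotation_params()
        for p in rng.integers(1, config.genome_length, size=400):
            p = int(p)
            expected, _g = classify_region("chr1", p, models, params)
            assert _CODE_TO_REGION[int(region_arr[p])] is expected, p


class TestSimulateCohort:
    def test_all_true_calls_pass_default_filters(self, small_dataset):
        truth = small_dataset["truth"]
        artifact_keys = {(r.sample, int(r.pos))
                         for r in truth.artifacts.itertuples()}
        for sid, rows in small_dataset["calls"].items():
            calls = [SomaticCall(sample_id=sid, **row) for row in rows]
            _passed, rejected = apply_somatic_filters(calls)
            for c, _reason in rejected:
                assert (sid, c.pos) in artifact_keys

    def test_spiked_artifacts_fail_with_their_reason(self, small_dataset):
        truth = small_dataset["truth"].artifacts
        by_key = {(r.sample, int(r.pos)): r.reason
                  for r in truth.itertuples()
                  if r.reason in ("low_support", "low_af", "low_ratio")}
        for sid, rows in small_dataset["calls"].items():
            calls = [SomaticCall(sample_id=sid, **row) for row in rows]
            _passed, rejected = apply_somatic_filters(calls)
            got = {(sid, c.pos): reason for c, reason in rejected}
            for key, reason in by_key.items():
                if key[0] == sid:
                    assert got.get(key) == reason

    def test_germline_and_pon_sites_are_flagged_and_dropped(self, small_dataset):
        from uvsomatic.io_formats import load_site_list

        germ = load_site_list(small_dataset["outdir"] / "germline_sites.tsv")
        pon = load_site_list(small_dataset["outdir"] / "pon_sites.tsv")
        n_flagged = 0
        for sid, rows in small_dataset["calls"].items():
            calls = [SomaticCall(sample_id=sid, **row) for row in rows]
            flag_sites(calls, germ, "germline")
            flag_sites(calls, pon, "pon")
            kept = drop_flagged(calls)
            n_flagged += len(calls) - len(kept)
        truth = small_dataset["truth"].artifacts
        expected = len(truth[truth.reason.isin(["germline", "pon"])])
        assert n_flagged == expected

    def test_dbs_fraction_zero_means_no_dbs_after_merging(self):
        config = tiny_config(dbs_fraction=0.0, n_artifacts_per_reason=0,
                             n_germline_sites=0, n_pon_sites=0)
        reference, models = generate_genome(config)
        calls, _ = simulate_cohort(config, reference, models)
        for sid, rows in calls.items():
            cs = [SomaticCall(sample_id=sid, **row) for row in rows]
            records = merge_adjacent_snvs(cs)
            assert all(r.mtype != "DBS" for r in records)

    def test_type_fractions_track_config_at_scale(self):
        config = SimulationConfig(
            seed=17, n_samples=10, n_genes=60, genome_length=500_000,
            lognorm_mu=7.3, n_near_empty=0, n_alkyl_dominant=1,
            planted_hotspots=[], planted_drivers=[],
            n_artifacts_per_reason=0, n_germline_sites=0, n_pon_sites=0,
        )
        reference, models = generate_genome(config)
        calls, truth = simulate_cohort(config, reference, models)
        records = []
        for sid, rows in calls.items():
            cs = [SomaticCall(sample_id=sid, **row) for row in rows]
            records.extend(merge_adjacent_snvs(cs))
        n = len(records)
        assert n > 10_000
        frac_dbs = sum(r.mtype == "DBS" for r in records) / n
        frac_ind = sum(r.mtype == "INDEL" for r in records) / n
        frac_sub = sum(r.mtype == "SNV" for r in records) / n
        assert frac_sub == pytest.approx(0.945, abs=0.01)
        assert frac_dbs == pytest.approx(0.037, abs=0.01)
        assert frac_ind == pytest.approx(0.018, abs=0.01)

    def test_mutations_confined_to_covered_windows(self, small_dataset):
        config = small_dataset["config"]
        mask = covered_mask(config, small_dataset["models"])
        for sid, rows in small_dataset["calls"].items():
            for row in rows:
                assert mask[row["pos"]], (sid, row)

    def test_signature_truth_recorded(self, small_dataset):
        truth = small_dataset["truth"].signatures
        assert truth["near_empty"].sum() == 1
        assert truth["alkyl_dominant"].sum() == 1
        assert ((truth["uv_weight"] >= 0) & (truth["uv_weight"] <= 1)).all()


class TestScoreTrack:
    def test_background_scores_and_planted_enrichment(self, small_dataset):
        track = small_dataset["track"]
        truth = small_dataset["truth"]
        df = track.df
        driver_pos = set()
        drv = truth.drivers
        for row in drv.itertuples():
            driver_pos.add(int(row.pos))
        planted = df[df["pos"].isin(driver_pos)]["score"]
        background = df[~df["pos"].isin(driver_pos)]["score"]
        assert planted.mean() > background.mean() + 0.4

    def test_deterministic_under_seed(self):
        config = tiny_config()
        reference, models = generate_genome(config)
        t1, _ = simulate_score_track(config, reference, models)
        t2, _ = simulate_score_track(config, reference, models)
        assert t1.df.equals(t2.df)


class TestGeneratedFilesParse:
    def test_fasta_gtf_vcf_round_trip_through_io(self, small_dataset):
        outdir = small_dataset["outdir"]
        reference = Reference.from_fasta(outdir / "genome.fa")
        config = small_dataset["config"]
        assert reference.length("chr1") == config.genome_length
        models = load_gene_models(outdir / "genes.gtf")
        orig = small_dataset["models"]
        assert set(models.transcripts) == set(orig.transcripts)
        for txid, tx in models.transcripts.items():
            assert tx.cds == orig.transcripts[txid].cds
            assert tx.utr5 == orig.transcripts[txid].utr5
        sid = config.sample_ids()[0]
        calls = load_somatic_calls(outdir / "vcf" / f"{sid}.vcf",
                                   f"{sid}_T", f"{sid}_N", sample_id=sid)
        assert len(calls) == len(small_dataset["calls"][sid])
        for call, row in zip(calls, small_dataset["calls"][sid]):
            assert (call.pos, call.ref, call.alt) == \
                (row["pos"], row["ref"], row["alt"])
            assert call.tumor_alt == row["tumor_alt"]
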