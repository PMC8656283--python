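"""End-to-end orchestration: filter -> merge -> annotate -> signatures ->
summary -> hotspots -> recurrent genes -> FM-bias -> MLPA.

Every stage writes its table under the output directory and the run ends
with a manifest recording the seed, input checksums and output checksums;
rerunning with the same inputs and seed reproduces byte-identical
non-log outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import (
    cohort_stats,
    fm_bias_driver,
    io_formats,
    mlpa_copynumber,
    mutation_classes,
    recurrence_hotspots,
    signature_fitting,
    somatic_filtering,
)
from .fm_bias_driver import FMBiasParams, ScoreTrack
from .gene_annotation import AnnotationParams
from .recurrence_hotspots import RecurrenceParams
from .somatic_filtering import FilterParams

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    vcf_dir: str
    gtf: str
    fasta: str
    outdir: str
    signature_matrix: str = None
    score_track: str = None
    germline_sites: str = None
    pon_sites: str = None
    mlpa_probes: str = None
    mlpa_tumor: str = None
    mlpa_normal: str = None
    hypermutated_genes: str = None
    samples: list = None  # default: every *.vcf in vcf_dir, id = stem
    tumor_suffix: str = "_T"
    normal_suffix: str = "_N"
    filter_params: FilterParams = field(default_factory=FilterParams)
    annotation_params: AnnotationParams = field(default_factory=AnnotationParams)
    recurrence_params: RecurrenceParams = field(default_factory=RecurrenceParams)
    fm_params: FMBiasParams = field(default_factory=FMBiasParams)
    min_signature_mutations: int = signature_fitting.DEFAULT_MIN_MUTATIONS
    coding_territory_mbp: float = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        nested = {
            "filter_params": FilterParams,
            "annotation_params": AnnotationParams,
            "recurrence_params": RecurrenceParams,
            "fm_params": FMBiasParams,
        }
        for key, value in raw.items():
            if key in nested:
                kwargs[key] = nested[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def for_dataset(cls, dataset_dir, outdir, seed: int = 0,
                    **overrides) -> "PipelineConfig":
        """Config pointing at a :func:`synthetic_data.generate_dataset` tree."""
        d = Path(dataset_dir)
        defaults = dict(
            vcf_dir=str(d / "vcf"),
            gtf=str(d / "genes.gtf"),
            fasta=str(d / "genome.fa"),
            outdir=str(outdir),
            signature_matrix=str(d / "signatures.tsv"),
            score_track=str(d / "score_track.tsv"),
            germline_sites=str(d / "germline_sites.tsv"),
            pon_sites=str(d / "pon_sites.tsv"),
            mlpa_probes=str(d / "mlpa_probes.tsv"),
            mlpa_tumor=str(d / "mlpa_tumor.tsv"),
            mlpa_normal=str(d / "mlpa_normal.tsv"),
            seed=seed,
        )
        defaults.update(overrides)
        cfg = cls(**defaults)
        cfg.fm_params.seed = seed
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df, path):
    df.to_csv(path, sep="\t", index=True, float_format="%.8g")


def run_pipeline(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = {}
    inputs = {}

    def record_input(name, path):
        if path:
            inputs[name] = {"path": str(path), "sha256": _sha256(path)}

    # --- load ---
    try:
        reference = io_formats.Reference.from_fasta(config.fasta)
        models = io_formats.load_gene_models(config.gtf)
        record_input("fasta", config.fasta)
        record_input("gtf", config.gtf)
        if config.samples:
            sample_specs = config.samples
        else:
            sample_specs = [
                (p.stem, str(p))
                for p in sorted(Path(config.vcf_dir).glob("*.vcf"))
            ]
        if not sample_specs:
            raise PipelineError("load", f"no VCFs under {config.vcf_dir}")
        calls = {}
        for sid, vcf_path in sample_specs:
            record_input(f"vcf:{sid}", vcf_path)
            calls[sid] = io_formats.load_somatic_calls(
                vcf_path, sid + config.tumor_suffix,
                sid + config.normal_suffix, sample_id=sid,
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc

    sample_ids = [sid for sid, _ in sample_specs]

    # --- filter ---
    try:
        germline = (io_formats.load_site_list(config.germline_sites)
                    if config.germline_sites else set())
        pon = (io_formats.load_site_list(config.pon_sites)
               if config.pon_sites else set())
        passed = {}
        reject_rows = []
        for sid in sample_ids:
            cs = calls[sid]
            somatic_filtering.flag_sites(cs, germline, "germline")
            somatic_filtering.flag_sites(cs, pon, "pon")
            kept = somatic_filtering.drop_flagged(cs)
            for c in cs:
                for f in c.flags & {"germline", "pon"}:
                    reject_rows.append((sid, c.chrom, c.pos, c.ref, c.alt, f))
            ok, rejected = somatic_filtering.apply_somatic_filters(
                kept, config.filter_params
            )
            passed[sid] = ok
            for c, reason in rejected:
                reject_rows.append((sid, c.chrom, c.pos, c.ref, c.alt, reason))
        import pandas as pd

        rej = pd.DataFrame(
            reject_rows,
            columns=["sample", "chrom", "pos", "ref", "alt", "reason"],
        ).sort_values(["sample", "chrom", "pos", "alt"], kind="mergesort")
        rej.to_csv(out / "rejected_calls.tsv", sep="\t", index=False)
        outputs["rejected_calls"] = out / "rejected_calls.tsv"
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc

    # --- merge + annotate ---
    try:
        records = []
        for sid in sample_ids:
            records.extend(mutation_classes.merge_adjacent_snvs(passed[sid]))
        mutation_classes.annotate_records(
            records, models, reference, config.annotation_params
        )
        io_formats.write_mutation_table(records, out / "mutations.tsv")
        outputs["mutations"] = out / "mutations.tsv"
    except Exception as exc:
        raise PipelineError("annotate", str(exc)) from exc

    # --- signatures ---
    try:
        if config.signature_matrix:
            sigmat = signature_fitting.SignatureMatrix.from_tsv(
                config.signature_matrix
            )
            record_input("signature_matrix", config.signature_matrix)
        else:
            sigmat = signature_fitting.uv_alkylation_signatures()
        by_sample = {sid: [] for sid in sample_ids}
        for r in records:
            by_sample[r.sample_id].append(r)
        profiles = [
            signature_fitting.build_96_profile(by_sample[sid], sid)
            for sid in sample_ids
        ]
        fits, excluded = signature_fitting.fit_cohort(
            profiles, sigmat, config.min_signature_mutations
        )
        signature_fitting.profiles_frame(profiles).to_csv(
            out / "profiles.tsv", sep="\t"
        )
        fits_df = signature_fitting.fits_frame(fits)
        fits_df.to_csv(out / "signature_fits.tsv", sep="\t", index=False,
                       float_format="%.6g")
        if excluded:
            logger.info("samples excluded from signature analysis: %s",
                        ",".join(excluded))
        outputs["profiles"] = out / "profiles.tsv"
        outputs["signature_fits"] = out / "signature_fits.tsv"
    except Exception as exc:
        raise PipelineError("signatures", str(exc)) from exc

    # --- cohort summary ---
    try:
        summary = cohort_stats.summarize_cohort(
            records, coding_territory_mbp=config.coding_territory_mbp
        )
        summary.to_csv(out / "cohort_summary.tsv", sep="\t")
        outputs["cohort_summary"] = out / "cohort_summary.tsv"
    except Exception as exc:
        raise PipelineError("summarize", str(exc)) from exc

    # --- hotspots + recurrent genes ---
    try:
        tallied = [r for r in records
                   if r.region in cohort_stats._REGION_BUCKET]
        hotspots = recurrence_hotspots.find_hotspots(
            tallied, config.recurrence_params
        )
        recurrence_hotspots.hotspots_frame(hotspots).to_csv(
            out / "hotspots.tsv", sep="\t", index=False
        )
        recurrence_hotspots.write_hotspots_bed(hotspots, out / "hotspots.bed")
        if config.hypermutated_genes:
            with open(config.hypermutated_genes) as fh:
                config.recurrence_params.hypermutated_exclusion |= {
                    line.strip() for line in fh if line.strip()
                }
            record_input("hypermutated_genes", config.hypermutated_genes)
        genes = recurrence_hotspots.find_frequently_mutated_genes(
            tallied, config.recurrence_params
        )
        recurrence_hotspots.recurrent_genes_frame(genes).to_csv(
            out / "recurrent_genes.tsv", sep="\t", index=False
        )
        outputs["hotspots"] = out / "hotspots.tsv"
        outputs["hotspots_bed"] = out / "hotspots.bed"
        outputs["recurrent_genes"] = out / "recurrent_genes.tsv"
    except Exception as exc:
        raise PipelineError("hotspots", str(exc)) from exc

    # --- FM bias ---
    if config.score_track:
        try:
            record_input("score_track", config.score_track)
            track = ScoreTrack.from_tsv(config.score_track)
            tables = fm_bias_driver.build_region_tables(
                track, models, reference, config.annotation_params
            )
            context_probs = signature_fitting.cohort_context_frequencies(
                records
            )
            config.fm_params.seed = config.seed
            results = fm_bias_driver.fm_bias_test(
                records, track, tables, context_probs, config.fm_params
            )
            fm_bias_driver.results_frame(results).to_csv(
                out / "fm_bias.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            outputs["fm_bias"] = out / "fm_bias.tsv"
        except Exception as exc:
            raise PipelineError("fm_bias", str(exc)) from exc

    # --- MLPA ---
    if config.mlpa_probes and config.mlpa_tumor and config.mlpa_normal:
        try:
            for name in ("mlpa_probes", "mlpa_tumor", "mlpa_normal"):
                record_input(name, getattr(config, name))
            probes = mlpa_copynumber.MLPAProbeSet.from_tsv(config.mlpa_probes)
            tumor = mlpa_copynumber.load_signal_table(config.mlpa_tumor)
            normal = mlpa_copynumber.load_signal_table(config.mlpa_normal)
            results = []
            for sid in sorted(tumor):
                res = mlpa_copynumber.normalize_mlpa(
                    tumor[sid], normal[sid], probes, sample_id=sid
                )
                mlpa_copynumber.call_cna(res)
                results.append(res)
            mlpa_copynumber.results_frame(results, probes).to_csv(
                out / "mlpa_copy_number.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            outputs["mlpa_copy_number"] = out / "mlpa_copy_number.tsv"
        except Exception as exc:
            raise PipelineError("mlpa", str(exc)) from exc

    manifest = {
        "seed": config.seed,
        "n_samples": len(sample_ids),
        "inputs": inputs,
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in sorted(outputs.items())
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
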