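"""Gene-subregion classification and coding-effect prediction.

Every position maps to exactly one region class with fixed priority
CODING > SPLICE_SITE > UTR5 > UTR3 > INTRON (> INTRON_DEEP) > INTERGENIC
when genes/transcripts overlap.  Intronic positions within
``splice_window`` nt of an exon boundary are splice sites and are counted
with coding mutations downstream; intronic positions deeper than
``intron_prox_window`` are labelled INTRON_DEEP and excluded from region
tallies (whole-exome capture does not cover them).  The full annotated
3'UTR is classified as UTR3 — recurrent 3'UTR mutations are observed well
past 100 nt downstream of the stop codon, so proximity windows model
capture in the simulator, not biology here.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .io_formats import GeneModelSet, Reference, ReferenceMismatchError, revcomp


class RegionClass(str, Enum):
    CODING = "CODING"
    SPLICE_SITE = "SPLICE_SITE"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    INTRON = "INTRON"
    INTRON_DEEP = "INTRON_DEEP"
    INTERGENIC = "INTERGENIC"

    def __str__(self):
        return self.value


#: region classes entering downstream tallies (splice sites count as coding)
TALLY_REGIONS = (
    RegionClass.CODING,
    RegionClass.SPLICE_SITE,
    RegionClass.UTR5,
    RegionClass.UTR3,
    RegionClass.INTRON,
    RegionClass.INTERGENIC,
)

_PRIORITY = {
    RegionClass.CODING: 0,
    RegionClass.SPLICE_SITE: 1,
    RegionClass.UTR5: 2,
    RegionClass.UTR3: 3,
    RegionClass.INTRON: 4,
    RegionClass.INTRON_DEEP: 5,
    RegionClass.INTERGENIC: 6,
}


@dataclass
class AnnotationParams:
    splice_window: int = 2
    intron_prox_window: int = 100
    utr3_prox_window: int = 100  # simulator coverage only; not a class cutoff

    def __post_init__(self):
        if self.splice_window > self.intron_prox_window:
            raise ValueError("splice_window must be <= intron_prox_window")


@dataclass
class CodingEffect:
    kind: str  # synonymous | missense | nonsense | stop_loss | frameshift | inframe_indel | splice
    protein: str = None  # e.g. "Ser24Phe"

    def __str__(self):
        return self.kind


NONSYNONYMOUS = {"missense", "nonsense", "stop_loss", "frameshift",
                 "inframe_indel", "splice"}


def _transcript_trees(models: GeneModelSet):
    """Per-chrom interval tree over canonical transcript spans (cached)."""
    cache = getattr(models, "_tx_trees", None)
    if cache is None:
        from intervaltree import IntervalTree

        cache = {}
        for tx in models.canonical_transcripts():
            tree = cache.setdefault(tx.chrom, IntervalTree())
            tree[tx.start : tx.end + 1] = tx
        models._tx_trees = cache
    return cache


def _classify_in_transcript(pos, tx, params):
    if tx.in_intervals(pos, tx.cds):
        return RegionClass.CODING
    if tx.in_intervals(pos, tx.utr5):
        return RegionClass.UTR5
    if tx.in_intervals(pos, tx.utr3):
        return RegionClass.UTR3
    d = tx.intron_distance(pos)
    if d is None:
        return None
    if d <= params.splice_window:
        return RegionClass.SPLICE_SITE
    if d <= params.intron_prox_window:
        return RegionClass.INTRON
    return RegionClass.INTRON_DEEP


def classify_region(chrom, pos, models: GeneModelSet,
                    params: AnnotationParams = None):
    """Classify a genomic position; returns (RegionClass, gene_id or None).

    Ambiguity across overlapping genes is resolved by the fixed priority
    order so that per-region tallies stay exclusive.
    """
    params = params or AnnotationParams()
    if pos < 1:
        raise ValueError("pos must be >= 1")
    trees = _transcript_trees(models)
    if chrom not in trees:
        if not any(tx.chrom == chrom for tx in models.transcripts.values()):
            # unknown to the models: still a valid intergenic position if
            # the caller's reference knows the contig; we cannot check here
            return RegionClass.INTERGENIC, None
    best = (RegionClass.INTERGENIC, None)
    for iv in trees.get(chrom, ()).at(pos) if chrom in trees else ():
        tx = iv.data
        cls = _classify_in_transcript(pos, tx, params)
        if cls is not None and _PRIORITY[cls] < _PRIORITY[best[0]]:
            best = (cls, tx.gene_id)
    return best


def intron_offset(chrom, pos, models: GeneModelSet, gene_id: str):
    """Distance of an intronic position to the nearest exon boundary."""
    tx = models.canonical(gene_id)
    return tx.intron_distance(pos)


def coding_effect(call, models: GeneModelSet, reference: Reference,
                  region: RegionClass = None,
                  gene_id: str = None,
                  params: AnnotationParams = None) -> CodingEffect:
    """Predict the coding effect of a call in a CODING/SPLICE_SITE region.

    Substitutions are translated through the standard genetic code on the
    coding strand of the canonical transcript; indels are typed purely by
    net length (frameshift unless divisible by 3).
    """
    params = params or AnnotationParams()
    if region is None or gene_id is None:
        region, gene_id = classify_region(call.chrom, call.pos, models, params)
    if region not in (RegionClass.CODING, RegionClass.SPLICE_SITE):
        raise ValueError(f"coding_effect undefined for region {region}")
    if region is RegionClass.SPLICE_SITE:
        return CodingEffect("splice")
    tx = models.canonical(gene_id)
    if not models.effect_eligible(tx.transcript_id):
        raise ValueError(
            f"transcript {tx.transcript_id} excluded from effect prediction"
        )
    ref_here = reference.seq(call.chrom, call.pos,
                             call.pos + len(call.ref) - 1)
    if ref_here != call.ref:
        raise ReferenceMismatchError(
            f"reference mismatch at {call.chrom}:{call.pos}: "
            f"expected {call.ref}, found {ref_here}"
        )
    if len(call.ref) != len(call.alt):
        net = abs(len(call.ref) - len(call.alt))
        return CodingEffect("frameshift" if net % 3 else "inframe_indel")
    return _substitution_effect(call, tx, reference)


def _cds_cache(tx, reference):
    cached = getattr(tx, "_cds_cache", None)
    if cached is None:
        cds_seq = tx.coding_sequence(reference)
        ref_prot = str(Seq(cds_seq).translate())
        cached = (cds_seq, ref_prot)
        tx._cds_cache = cached
    return cached


def _substitution_effect(call, tx, reference) -> CodingEffect:
    cds_seq, ref_prot = _cds_cache(tx, reference)
    # only the touched codons can change; retranslate just those
    changed = {}
    for offset in range(len(call.ref)):
        idx = tx.cds_index(call.pos + offset)
        if idx is None:
            continue  # base of a multi-nt substitution outside the CDS
        base = call.alt[offset]
        changed[idx] = base if tx.strand == "+" else revcomp(base)
    codons = sorted({idx // 3 for idx in changed})
    diffs = []
    for ci in codons:
        codon = list(cds_seq[3 * ci : 3 * ci + 3])
        for k in range(3):
            if 3 * ci + k in changed:
                codon[k] = changed[3 * ci + k]
        aa = str(Seq("".join(codon)).translate())
        if aa != ref_prot[ci]:
            diffs.append((ci, aa))
    if not diffs:
        return CodingEffect("synonymous")
    i, aa = diffs[0]
    descriptor = f"{seq3(ref_prot[i])}{i + 1}{seq3(aa)}"
    stop_idx = ref_prot.find("*")
    if any(aa == "*" for j, aa in diffs if stop_idx < 0 or j < stop_idx):
        return CodingEffect("nonsense", descriptor)
    if any(ref_prot[j] == "*" for j, _ in diffs):
        return CodingEffect("stop_loss", descriptor)
    return CodingEffect("missense", descriptor)
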