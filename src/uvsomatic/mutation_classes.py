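"""Mutation typing: DBS merging, HGVS-like labels, trinucleotide contexts.

Adjacent same-sample single-nucleotide substitutions are merged (after
filtering, transitively) into double substitutions annotated as HGVS
"delins" variants — the CC>TT double substitution being the hallmark of
UV-induced pyrimidine-dimer mutagenesis.  Single-base contexts are
pyrimidine-normalized into the standard 96-channel encoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import GeneModelSet, Reference, revcomp
from .gene_annotation import (
    AnnotationParams,
    RegionClass,
    classify_region,
    coding_effect,
)

logger = logging.getLogger(__name__)

SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"

#: the 96 standard context labels in fixed lexicographic channel order
CONTEXT_LABELS = [
    f"{five}[{sub}]{three}"
    for sub in SUB_CLASSES
    for five in BASES
    for three in BASES
]

_CLASS_INDEX = {s: i for i, s in enumerate(SUB_CLASSES)}
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: <4 nt is a "short" indel; longer ones are retained but flagged
SHORT_INDEL_MAX = 3


@dataclass
class MutationRecord:
    """Filtered, possibly merged mutation with type and annotations."""

    sample_id: str
    chrom: str
    start: int
    end: int
    ref: str
    alt: str
    mtype: str  # SNV | DBS | INDEL
    region: RegionClass = None
    effect: object = None  # CodingEffect or None
    gene_id: str = None
    hgvs_c: str = ""
    context_index: int = None
    is_cc_tt: bool = False
    tumor_alt: int = 0
    tumor_depth: int = 0
    intron_offset: int = None
    long_indel: bool = False
    merged_from: int = 1

    def __post_init__(self):
        if self.mtype == "SNV" and self.end - self.start != 0:
            raise ValueError("SNV must span one position")
        if self.mtype == "DBS" and not (
            self.end - self.start == 1
            and len(self.ref) == 2
            and len(self.alt) == 2
        ):
            raise ValueError("DBS must span two positions with 2-nt alleles")
        if self.is_cc_tt and self.mtype != "DBS":
            raise ValueError("is_cc_tt only applies to DBS records")

    @property
    def pos(self) -> int:
        return self.start

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def tumor_af(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else 0.0


def context_index_of(five: str, ref: str, alt: str, three: str) -> int:
    """Channel index 0-95 after pyrimidine normalization."""
    if ref in "AG":
        ref, alt = _COMP[ref], _COMP[alt]
        five, three = _COMP[three], _COMP[five]
    sub = f"{ref}>{alt}"
    return (
        _CLASS_INDEX[sub] * 16
        + _BASE_INDEX[five] * 4
        + _BASE_INDEX[three]
    )


def trinucleotide_context(record: MutationRecord, reference: Reference) -> int:
    """Pyrimidine-normalized 96-channel context of an SNV record."""
    if record.mtype != "SNV":
        raise ValueError("trinucleotide context is defined for SNVs only")
    pos = record.start
    if pos <= 1 or pos >= reference.length(record.chrom):
        raise ValueError(
            f"no flanking base at {record.chrom}:{pos} (contig edge)"
        )
    five = reference.base(record.chrom, pos - 1)
    three = reference.base(record.chrom, pos + 1)
    return context_index_of(five, record.ref, record.alt, three)


# ---------------------------------------------------------------------------
# Merging adjacent SNVs into double substitutions
# ---------------------------------------------------------------------------

def _call_record(call, mtype, start=None, end=None, ref=None, alt=None,
                 merged_from=1):
    ref = call.ref if ref is None else ref
    alt = call.alt if alt is None else alt
    rec = MutationRecord(
        sample_id=call.sample_id,
        chrom=call.chrom,
        start=call.pos if start is None else start,
        end=(call.pos + len(call.ref) - 1) if end is None else end,
        ref=ref,
        alt=alt,
        mtype=mtype,
        is_cc_tt=(mtype == "DBS" and (ref, alt) in (("CC", "TT"), ("GG", "AA"))),
        tumor_alt=call.tumor_alt,
        tumor_depth=call.tumor_depth,
        merged_from=merged_from,
    )
    if mtype == "INDEL":
        rec.long_indel = rec.indel_length > SHORT_INDEL_MAX
    return rec


def merge_adjacent_snvs(calls) -> list:
    """Turn one sample's filtered calls into MutationRecords, merging
    runs of directly adjacent SNVs.

    Runs of length 2 become DBS records; longer runs become a single
    multi-nucleotide "delins" record typed INDEL (logged).  All other
    calls map 1:1.
    """
    seen = set()
    for c in calls:
        k = (c.sample_id, c.chrom, c.pos, c.alt)
        if k in seen:
            raise ValueError(f"duplicate call {k}")
        seen.add(k)
    calls = sorted(calls, key=lambda c: (c.sample_id, c.chrom, c.pos))

    records = []
    run = []

    def flush():
        if not run:
            return
        if len(run) == 1:
            records.append(_call_record(run[0], "SNV"))
        else:
            ref = "".join(c.ref for c in run)
            alt = "".join(c.alt for c in run)
            first = run[0]
            mtype = "DBS" if len(run) == 2 else "INDEL"
            if len(run) > 2:
                logger.info(
                    "run of %d adjacent SNVs at %s:%d merged as delins",
                    len(run), first.chrom, first.pos,
                )
            records.append(
                _call_record(first, mtype, start=first.pos,
                             end=run[-1].pos, ref=ref, alt=alt,
                             merged_from=len(run))
            )
        run.clear()

    for call in calls:
        if not call.is_snv:
            flush()
            if len(call.ref) == len(call.alt):  # pre-formed MNV in input
                mtype = "DBS" if len(call.ref) == 2 else "INDEL"
                records.append(_call_record(call, mtype))
            else:
                records.append(_call_record(call, "INDEL"))
            continue
        if run and (call.sample_id != run[-1].sample_id
                    or call.chrom != run[-1].chrom
                    or call.pos != run[-1].pos + 1):
            flush()
        run.append(call)
    flush()
    return records


# ---------------------------------------------------------------------------
# HGVS-like coding-strand labels
# ---------------------------------------------------------------------------

def _exonic_label(tx, pos: int) -> str:
    t = tx.transcript_index(pos)
    cstart = tx.cds_start_tindex()
    cend = tx.cds_end_tindex()
    if t < cstart:
        return f"-{cstart - t}"
    if t > cend:
        return f"*{t - cend}"
    return str(t - cstart + 1)


def _position_label(tx, pos: int) -> str:
    if tx.exonic(pos):
        return _exonic_label(tx, pos)
    prev_end = max((e for s, e in tx.exons if e < pos), default=None)
    next_start = min((s for s, e in tx.exons if s > pos), default=None)
    if prev_end is None or next_start is None:
        raise ValueError(f"position {pos} outside transcript {tx.transcript_id}")
    d_prev, d_next = pos - prev_end, next_start - pos
    if tx.strand == "+":
        if d_prev <= d_next:
            return f"{_exonic_label(tx, prev_end)}+{d_prev}"
        return f"{_exonic_label(tx, next_start)}-{d_next}"
    if d_next <= d_prev:
        return f"{_exonic_label(tx, next_start)}+{d_next}"
    return f"{_exonic_label(tx, prev_end)}-{d_prev}"


def hgvs_label(record: MutationRecord, models: GeneModelSet) -> str:
    """c.-N / c.N / c.*N style label on the canonical-transcript coding strand."""
    if record.gene_id is None:
        raise ValueError("record is not gene-associated")
    tx = models.canonical(record.gene_id)
    minus = tx.strand == "-"

    def coding_allele(s):
        return revcomp(s) if minus else s

    if record.mtype == "SNV":
        lab = _position_label(tx, record.start)
        return f"c.{lab}{coding_allele(record.ref)}>{coding_allele(record.alt)}"

    if len(record.ref) == len(record.alt):  # DBS or longer multi-sub
        p1, p2 = record.start, record.end
        if minus:
            p1, p2 = p2, p1
        l1, l2 = _position_label(tx, p1), _position_label(tx, p2)
        return f"c.{l1}_{l2}delins{coding_allele(record.alt)}"

    if len(record.ref) > len(record.alt):  # anchored deletion
        del_start, del_end = record.start + len(record.alt), record.end
        p1, p2 = (del_end, del_start) if minus else (del_start, del_end)
        l1 = _position_label(tx, p1)
        if del_start == del_end:
            return f"c.{l1}del"
        l2 = _position_label(tx, p2)
        return f"c.{l1}_{l2}del"

    # anchored insertion: inserted sequence sits between pos and pos+1
    ins = record.alt[len(record.ref):]
    left, right = record.start, record.start + 1
    if minus:
        left, right = right, left
        ins = revcomp(ins)
    l1, l2 = _position_label(tx, left), _position_label(tx, right)
    return f"c.{l1}_{l2}ins{ins}"


# ---------------------------------------------------------------------------
# Whole-record annotation
# ---------------------------------------------------------------------------

def annotate_records(records, models: GeneModelSet, reference: Reference,
                     params: AnnotationParams = None):
    """Fill region, gene, effect, context and HGVS fields in place."""
    params = params or AnnotationParams()
    for rec in records:
        region, gene_id = classify_region(rec.chrom, rec.start, models, params)
        rec.region = region
        rec.gene_id = gene_id
        if region in (RegionClass.INTRON, RegionClass.SPLICE_SITE,
                      RegionClass.INTRON_DEEP) and gene_id is not None:
            tx = models.canonical(gene_id)
            rec.intron_offset = tx.intron_distance(rec.start)
        if region in (RegionClass.CODING, RegionClass.SPLICE_SITE):
            try:
                rec.effect = coding_effect(
                    rec, models, reference, region=region, gene_id=gene_id,
                    params=params,
                )
            except ValueError:
                rec.effect = None  # e.g. transcript excluded (CDS % 3 != 0)
        if rec.mtype == "SNV":
            rec.context_index = trinucleotide_context(rec, reference)
        if gene_id is not None:
            try:
                rec.hgvs_c = hgvs_label(rec, models)
            except ValueError:
                # events spanning past a transcript edge have no anchor
                rec.hgvs_c = ""
    return records
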