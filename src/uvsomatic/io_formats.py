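"""Readers/writers for the standard formats the pipeline touches.

All external coordinates are 1-based inclusive (VCF/GTF convention).
Allelic depth is taken from the per-sample AD FORMAT field; depth is
``sum(AD)`` rather than DP so that allele fractions are self-consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "."

MUTATION_TABLE_COLUMNS = [
    "sample", "chrom", "pos", "end", "ref", "alt", "type", "region",
    "effect", "gene", "hgvs_c", "context", "tumor_alt", "tumor_depth",
]


class ReferenceMismatchError(ValueError):
    pass


@dataclass
class SomaticCall:
    """One tumor/normal variant observation with allelic read support."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    tumor_alt: int
    tumor_depth: int
    normal_alt: int
    normal_depth: int
    flags: set = field(default_factory=set)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("allele strings must be nonempty")
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if not (0 <= self.tumor_alt <= self.tumor_depth):
            raise ValueError("tumor_alt outside [0, tumor_depth]")
        if not (0 <= self.normal_alt <= self.normal_depth):
            raise ValueError("normal_alt outside [0, normal_depth]")

    @property
    def tumor_af(self) -> float:
        if self.tumor_depth == 0:
            raise ValueError(f"uncovered site {self.chrom}:{self.pos}")
        return self.tumor_alt / self.tumor_depth

    @property
    def normal_af(self) -> float:
        if self.normal_depth == 0:
            return 0.0
        return self.normal_alt / self.normal_depth

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class Transcript:
    """One transcript with ordered exon/CDS/UTR intervals (1-based, inclusive)."""

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: list  # [(start, end)] sorted genomically
    cds: list
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)

    def __post_init__(self):
        self.exons = sorted(tuple(x) for x in self.exons)
        self.cds = sorted(tuple(x) for x in self.cds)
        self.utr5 = sorted(tuple(x) for x in self.utr5)
        self.utr3 = sorted(tuple(x) for x in self.utr3)
        for a, b in zip(self.exons, self.exons[1:]):
            if a[1] >= b[0]:
                raise ValueError(f"{self.transcript_id}: overlapping exons {a} {b}")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_intervals(self, pos: int, intervals) -> bool:
        return any(s <= pos <= e for s, e in intervals)

    def exonic(self, pos: int) -> bool:
        return self.in_intervals(pos, self.exons)

    def intron_distance(self, pos: int):
        """Distance (>=1) from an intronic position to the nearest exon edge.

        Returns None when the position is exonic or outside the transcript.
        """
        if not self.contains(pos) or self.exonic(pos):
            return None
        dist = None
        for s, e in self.exons:
            if e < pos:
                d = pos - e
            elif s > pos:
                d = s - pos
            else:  # pragma: no cover - exonic handled above
                continue
            dist = d if dist is None else min(dist, d)
        return dist

    # --- transcript/CDS coordinate machinery (strand aware) ---

    def _transcript_order(self, intervals):
        ivs = list(intervals)
        return ivs if self.strand == "+" else list(reversed(ivs))

    def transcript_index(self, pos: int):
        """0-based index of an exonic genomic position in the spliced mRNA."""
        off = 0
        for s, e in self._transcript_order(self.exons):
            if s <= pos <= e:
                return off + (pos - s if self.strand == "+" else e - pos)
            off += e - s + 1
        return None

    def cds_index(self, pos: int):
        """0-based index of a genomic position within the coding sequence."""
        off = 0
        for s, e in self._transcript_order(self.cds):
            if s <= pos <= e:
                return off + (pos - s if self.strand == "+" else e - pos)
            off += e - s + 1
        return None

    def cds_start_tindex(self) -> int:
        first = self._transcript_order(self.cds)[0]
        pos = first[0] if self.strand == "+" else first[1]
        return self.transcript_index(pos)

    def cds_end_tindex(self) -> int:
        last = self._transcript_order(self.cds)[-1]
        pos = last[1] if self.strand == "+" else last[0]
        return self.transcript_index(pos)

    def coding_sequence(self, reference) -> str:
        parts = []
        for s, e in self._transcript_order(self.cds):
            seg = reference.seq(self.chrom, s, e)
            if self.strand == "-":
                seg = revcomp(seg)
            parts.append(seg)
        return "".join(parts)


@dataclass
class GeneModelSet:
    """Genes/transcripts used for region classification and effect prediction.

    The canonical transcript of a gene is the one with the longest CDS
    (override with ``canonical_overrides``); only canonical transcripts are
    used for effect prediction and HGVS labelling.
    """

    transcripts: dict  # transcript_id -> Transcript
    canonical_overrides: dict = field(default_factory=dict)
    excluded_transcripts: set = field(default_factory=set)

    def __post_init__(self):
        self.genes = {}
        for tx in self.transcripts.values():
            self.genes.setdefault(tx.gene_id, []).append(tx.transcript_id)
        self._canonical = {}
        for gid, txids in self.genes.items():
            if gid in self.canonical_overrides:
                self._canonical[gid] = self.canonical_overrides[gid]
            else:
                self._canonical[gid] = max(
                    txids, key=lambda t: (self.transcripts[t].cds_length, t)
                )

    def gene_ids(self):
        return sorted(self.genes)

    def canonical(self, gene_id: str) -> Transcript:
        return self.transcripts[self._canonical[gene_id]]

    def canonical_transcripts(self):
        return [self.canonical(g) for g in self.gene_ids()]

    def effect_eligible(self, transcript_id: str) -> bool:
        return transcript_id not in self.excluded_transcripts


class Reference:
    """Reference sequence handle with 1-based inclusive ``seq``/``base``."""

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = {k: str(v).upper() for k, v in contigs.items()}

    @classmethod
    def from_fasta(cls, path) -> "Reference":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def contig_names(self):
        return list(self._contigs)

    def __contains__(self, chrom):
        return chrom in self._contigs

    def length(self, chrom: str) -> int:
        return len(self._contigs[chrom])

    def seq(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._contigs:
            raise KeyError(f"unknown contig {chrom!r}")
        if start < 1 or end > len(self._contigs[chrom]):
            raise ValueError(f"range {start}-{end} outside {chrom}")
        return self._contigs[chrom][start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        return self.seq(chrom, pos, pos)


@dataclass
class Cohort:
    """Multi-sample container: ordered samples, their calls, reference, models."""

    sample_ids: list
    calls: dict  # sample_id -> list[SomaticCall]
    reference: Reference
    models: GeneModelSet

    def __post_init__(self):
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        for sid in self.sample_ids:
            for call in self.calls.get(sid, []):
                if call.chrom not in self.reference:
                    raise ValueError(
                        f"call contig {call.chrom!r} missing from reference"
                    )

    def all_calls(self):
        for sid in self.sample_ids:
            yield from self.calls.get(sid, [])


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def load_somatic_calls(vcf_path, tumor_sample: str, normal_sample: str,
                       sample_id: str = None):
    """Read tumor/normal calls from a VCF with per-sample AD entries.

    Multi-allelic records are decomposed into one :class:`SomaticCall` per
    alternate allele; the AD entry of an alternate is matched by allele
    index.  Depth is ``sum(AD)``.  ``sample_id`` labels the resulting
    calls (default: the tumor column name).
    """
    sample_id = sample_id or tumor_sample
    from cyvcf2 import VCF

    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise FileNotFoundError(str(vcf_path))
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for name in (tumor_sample, normal_sample):
        if name not in samples:
            raise KeyError(f"sample {name!r} absent from VCF header {samples}")
    t_idx = samples.index(tumor_sample)
    n_idx = samples.index(normal_sample)

    calls = []
    for rec in vcf:
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ValueError(
                f"missing allelic depth (AD) at {rec.CHROM}:{rec.POS}"
            )
        t_ad = [int(x) for x in ad[t_idx] if int(x) >= 0]
        n_ad = [int(x) for x in ad[n_idx] if int(x) >= 0]
        n_alleles = 1 + len(rec.ALT)
        if len(t_ad) != n_alleles or len(n_ad) != n_alleles:
            raise ValueError(
                f"malformed AD at {rec.CHROM}:{rec.POS}: expected "
                f"{n_alleles} entries"
            )
        for i, alt in enumerate(rec.ALT, start=1):
            calls.append(
                SomaticCall(
                    sample_id=sample_id,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    tumor_alt=t_ad[i],
                    tumor_depth=sum(t_ad),
                    normal_alt=n_ad[i],
                    normal_depth=sum(n_ad),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Gene models (GTF)
# ---------------------------------------------------------------------------

def load_gene_models(path) -> GeneModelSet:
    """Build a :class:`GeneModelSet` from a GTF with exon and CDS features.

    UTR intervals are derived as exon minus CDS, split into 5'/3' by strand.
    Transcripts whose CDS length is not divisible by 3 are excluded from
    effect prediction (logged), as are CDS features outside any exon
    (error).
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    per_tx = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        txid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        gname = feat.attributes.get("gene_name", [gid])[0]
        entry = per_tx.setdefault(
            txid,
            {"gene_id": gid, "gene_name": gname, "chrom": feat.seqid,
             "strand": feat.strand, "exons": [], "cds": []},
        )
        key = "exons" if feat.featuretype == "exon" else "cds"
        entry[key].append((feat.start, feat.end))
    transcripts = {}
    excluded = set()
    for txid, entry in per_tx.items():
        exons = sorted(entry["exons"])
        cds = sorted(entry["cds"])
        for cs, ce in cds:
            if not any(s <= cs and ce <= e for s, e in exons):
                raise ValueError(f"{txid}: CDS {cs}-{ce} outside any exon")
        utr5, utr3 = _derive_utrs(exons, cds, entry["strand"])
        tx = Transcript(
            transcript_id=txid,
            gene_id=entry["gene_id"],
            gene_name=entry["gene_name"],
            chrom=entry["chrom"],
            strand=entry["strand"],
            exons=exons,
            cds=cds,
            utr5=utr5,
            utr3=utr3,
        )
        if cds and tx.cds_length % 3 != 0:
            logger.warning(
                "transcript %s: CDS length %d not divisible by 3; "
                "excluded from effect prediction", txid, tx.cds_length
            )
            excluded.add(txid)
        transcripts[txid] = tx
    return GeneModelSet(transcripts=transcripts, excluded_transcripts=excluded)


def _derive_utrs(exons, cds, strand):
    """Exonic bases outside the CDS, split into 5' and 3' sides by strand."""
    if not cds:
        return [], []
    cds_start, cds_end = cds[0][0], cds[-1][1]
    left, right = [], []
    for s, e in exons:
        if s < cds_start:
            left.append((s, min(e, cds_start - 1)))
        if e > cds_end:
            right.append((max(s, cds_end + 1), e))
    if strand == "+":
        return left, right
    return right, left


# ---------------------------------------------------------------------------
# Mutation table (TSV)
# ---------------------------------------------------------------------------

def mutation_records_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "sample": r.sample_id,
                "chrom": r.chrom,
                "pos": r.start,
                "end": r.end,
                "ref": r.ref,
                "alt": r.alt,
                "type": r.mtype,
                "region": r.region if r.region is not None else MISSING,
                "effect": r.effect if r.effect is not None else MISSING,
                "gene": r.gene_id if r.gene_id is not None else MISSING,
                "hgvs_c": r.hgvs_c if r.hgvs_c else MISSING,
                "context": r.context_index if r.context_index is not None else MISSING,
                "tumor_alt": r.tumor_alt,
                "tumor_depth": r.tumor_depth,
            }
        )
    df = pd.DataFrame(rows, columns=MUTATION_TABLE_COLUMNS)
    if len(df):
        df = df.sort_values(["chrom", "pos", "sample"], kind="mergesort")
    return df.reset_index(drop=True)


def write_mutation_table(records, path) -> None:
    """Write annotated records as TSV ordered by (chrom, pos, sample)."""
    df = mutation_records_frame(records)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_mutation_table(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=[MISSING], keep_default_na=False,
        dtype={"chrom": str, "sample": str},
    )


# ---------------------------------------------------------------------------
# Site lists (germline / panel-of-normals)
# ---------------------------------------------------------------------------

def load_site_list(path) -> set:
    """Load (chrom, pos, ref, alt) keys from a 4-column TSV or sites-only VCF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    sites = set()
    with open(path) as fh:
        first = fh.readline()
        is_vcf = first.startswith("##fileformat=VCF")
        fh.seek(0)
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if is_vcf:
                chrom, pos, _id, ref, alts = parts[:5]
                for alt in alts.split(","):
                    sites.add((chrom, int(pos), ref.upper(), alt.upper()))
            else:
                chrom, pos, ref, alt = parts[:4]
                sites.add((chrom, int(pos), ref.upper(), alt.upper()))
    return sites


def write_site_list(sites: Iterable[tuple], path) -> None:
    rows = sorted(sites)
    with open(path, "w") as fh:
        for chrom, pos, ref, alt in rows:
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


# ---------------------------------------------------------------------------
# FASTA writing (simulator output; reading goes through pyfaidx)
# ---------------------------------------------------------------------------

def write_fasta(contigs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
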