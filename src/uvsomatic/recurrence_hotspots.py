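"""Hotspot and frequently-mutated-gene identification.

A hotspot is a genomic position mutated in at least ``hotspot_min_samples``
distinct samples; mutations at directly adjacent nucleotides are merged
(transitively) into one hotspot whose sample count is the union of carrier
samples.  Gene-level recurrence uses region-specific sample thresholds,
counts distinct samples (multiplicity within a sample is ignored), and
drops genes on a hypermutated-passenger exclusion list before
thresholding.  Splice-site mutations count with coding mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .gene_annotation import NONSYNONYMOUS, RegionClass


@dataclass
class RecurrenceParams:
    hotspot_min_samples: int = 3
    cds_min_samples: int = 5
    utr5_min_samples: int = 4
    utr3_min_samples: int = 4
    intron_min_samples: int = 5
    intron_recurrence_window: int = 40
    merge_distance: int = 1
    hypermutated_exclusion: set = field(default_factory=set)

    def __post_init__(self):
        for name in ("hotspot_min_samples", "cds_min_samples",
                     "utr5_min_samples", "utr3_min_samples",
                     "intron_min_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        self.hypermutated_exclusion = set(self.hypermutated_exclusion)


@dataclass
class Hotspot:
    chrom: str
    start: int
    end: int
    n_samples: int
    samples: tuple
    mutations: list

    @property
    def positions(self):
        return range(self.start, self.end + 1)


@dataclass
class RecurrentGene:
    gene_id: str
    region: str  # CODING | UTR5 | UTR3 | INTRON
    n_samples: int
    n_mutations: int
    samples: tuple


def _record_positions(rec):
    """Genomic positions a record occupies for hotspot purposes.

    A DBS (or longer substitution) contributes its full span; an indel is
    anchored at its start position.
    """
    if len(rec.ref) == len(rec.alt):
        return range(rec.start, rec.end + 1)
    return (rec.start,)


def find_hotspots(records, params: RecurrenceParams = None):
    """Merge per-position sample sets into hotspots of >= threshold samples."""
    params = params or RecurrenceParams()
    per_pos = {}  # (chrom, pos) -> {"samples": set, "mutations": list}
    for rec in records:
        for pos in _record_positions(rec):
            entry = per_pos.setdefault(
                (rec.chrom, pos), {"samples": set(), "mutations": []}
            )
            entry["samples"].add(rec.sample_id)
            entry["mutations"].append(rec)

    hotspots = []
    for chrom in sorted({c for c, _ in per_pos}):
        positions = sorted(p for c, p in per_pos if c == chrom)
        cluster = []
        for pos in positions:
            if cluster and pos - cluster[-1] > params.merge_distance:
                hotspots.extend(_emit(chrom, cluster, per_pos, params))
                cluster = []
            cluster.append(pos)
        if cluster:
            hotspots.extend(_emit(chrom, cluster, per_pos, params))
    return hotspots


def _emit(chrom, cluster, per_pos, params):
    """Yield the cluster as a hotspot if its carrier-sample union reaches
    the threshold (the union bounds every per-position count from above)."""
    samples = set()
    mutations = []
    for pos in cluster:
        entry = per_pos[(chrom, pos)]
        samples |= entry["samples"]
        mutations.extend(entry["mutations"])
    if len(samples) >= params.hotspot_min_samples:
        seen, uniq = set(), []
        for m in mutations:
            if id(m) not in seen:
                seen.add(id(m))
                uniq.append(m)
        yield Hotspot(
            chrom=chrom, start=cluster[0], end=cluster[-1],
            n_samples=len(samples), samples=tuple(sorted(samples)),
            mutations=uniq,
        )


_GENE_REGION_OF = {
    RegionClass.CODING: "CODING",
    RegionClass.SPLICE_SITE: "CODING",  # splice sites count as coding
    RegionClass.UTR5: "UTR5",
    RegionClass.UTR3: "UTR3",
    RegionClass.INTRON: "INTRON",
}

_REGION_THRESHOLD_ATTR = {
    "CODING": "cds_min_samples",
    "UTR5": "utr5_min_samples",
    "UTR3": "utr3_min_samples",
    "INTRON": "intron_min_samples",
}


def qualifies(rec, params: RecurrenceParams):
    """(gene-region, qualifying?) for one annotated record."""
    region = _GENE_REGION_OF.get(rec.region)
    if region is None or rec.gene_id is None:
        return None, False
    if region == "CODING":
        ok = rec.effect is not None and rec.effect.kind in NONSYNONYMOUS
    elif region == "INTRON" and rec.region is RegionClass.INTRON:
        ok = (rec.intron_offset is not None
              and rec.intron_offset <= params.intron_recurrence_window)
    else:
        ok = True
    return region, ok


def find_frequently_mutated_genes(records, params: RecurrenceParams = None):
    """Per gene and region, distinct samples with qualifying mutations."""
    params = params or RecurrenceParams()
    tally = {}  # (gene, region) -> {"samples": set, "n": int}
    for rec in records:
        region, ok = qualifies(rec, params)
        if not ok or rec.gene_id in params.hypermutated_exclusion:
            continue
        entry = tally.setdefault((rec.gene_id, region),
                                 {"samples": set(), "n": 0})
        entry["samples"].add(rec.sample_id)
        entry["n"] += 1

    out = []
    for (gene, region), entry in sorted(tally.items()):
        threshold = getattr(params, _REGION_THRESHOLD_ATTR[region])
        if len(entry["samples"]) >= threshold:
            out.append(
                RecurrentGene(
                    gene_id=gene, region=region,
                    n_samples=len(entry["samples"]),
                    n_mutations=entry["n"],
                    samples=tuple(sorted(entry["samples"])),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Tabular / BED output
# ---------------------------------------------------------------------------

def hotspots_frame(hotspots) -> pd.DataFrame:
    rows = [
        {"chrom": h.chrom, "start": h.start, "end": h.end,
         "n_samples": h.n_samples, "samples": ",".join(h.samples)}
        for h in hotspots
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "n_samples", "samples"])


def write_hotspots_bed(hotspots, path) -> None:
    """BED (0-based half-open) with the sample count as score."""
    with open(path, "w") as fh:
        for h in hotspots:
            fh.write(f"{h.chrom}\t{h.start - 1}\t{h.end}\t"
                     f"hotspot\t{h.n_samples}\t.\n")


def recurrent_genes_frame(genes) -> pd.DataFrame:
    rows = [
        {"gene": g.gene_id, "region": g.region, "n_samples": g.n_samples,
         "n_mutations": g.n_mutations, "samples": ",".join(g.samples)}
        for g in genes
    ]
    return pd.DataFrame(rows, columns=["gene", "region", "n_samples",
                                       "n_mutations", "samples"])
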