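"""Cohort-level summaries and the region-enrichment Fisher test.

The summary table mirrors the classic per-region layout: counts and
percentages of mutations split by region (coding incl. splice sites vs.
the noncoding buckets) and by type (single substitution, double
substitution, short indel), mean sequencing coverage of mutated positions,
mean alternate-allele fraction, and per-sample mutation burden over the
coding territory.  Percentages are rounded half-up to one decimal, the
convention of such tables.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import scipy.stats

from .gene_annotation import RegionClass
from .mutation_classes import SHORT_INDEL_MAX

SUMMARY_REGIONS = ["all", "coding", "noncoding", "introns", "3'UTR",
                   "5'UTR", "intergenic"]

_REGION_BUCKET = {
    RegionClass.CODING: "coding",
    RegionClass.SPLICE_SITE: "coding",
    RegionClass.UTR5: "5'UTR",
    RegionClass.UTR3: "3'UTR",
    RegionClass.INTRON: "introns",
    RegionClass.INTERGENIC: "intergenic",
}

NONCODING_BUCKETS = ("introns", "3'UTR", "5'UTR", "intergenic")


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Half-up percentage rounding, e.g. percent(42380, 84571) == 50.1."""
    if total == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(q, ROUND_HALF_UP)
    )


def _type_of(rec) -> str:
    if rec.mtype == "SNV":
        return "substitution"
    if rec.mtype == "DBS":
        return "double_substitution"
    if rec.indel_length <= SHORT_INDEL_MAX and len(rec.ref) != len(rec.alt):
        return "short_indel"
    return "other"


def summarize_cohort(records, coding_territory_mbp: float = None) -> pd.DataFrame:
    """Region x type counts/percentages plus coverage, AF and burden.

    ``records`` must be annotated; records classified INTRON_DEEP are
    outside the tallies.  Coverage and allele fraction are unweighted
    means over mutations (mutation-weighted).  Burden is the mean
    per-sample count of coding-region mutations per Mbp of coding
    territory, reported only when the territory is given.
    """
    if coding_territory_mbp is not None and coding_territory_mbp <= 0:
        raise ValueError("coding_territory_mbp must be > 0")
    tallied = [r for r in records if r.region in _REGION_BUCKET]
    rows = {}
    for name in SUMMARY_REGIONS:
        rows[name] = {
            "n_mutations": 0, "substitution": 0, "double_substitution": 0,
            "short_indel": 0, "other": 0, "_depths": [], "_afs": [],
        }

    def add(bucket, rec):
        row = rows[bucket]
        row["n_mutations"] += 1
        row[_type_of(rec)] += 1
        if rec.tumor_depth:
            row["_depths"].append(rec.tumor_depth)
            row["_afs"].append(rec.tumor_af)

    for rec in tallied:
        bucket = _REGION_BUCKET[rec.region]
        add("all", rec)
        add(bucket, rec)
        if bucket in NONCODING_BUCKETS:
            add("noncoding", rec)

    total = rows["all"]["n_mutations"]
    out = []
    for name in SUMMARY_REGIONS:
        row = rows[name]
        n = row["n_mutations"]
        out.append(
            {
                "region": name,
                "n_mutations": n,
                "pct_of_total": percent(n, total),
                "mean_coverage": (round(float(np.mean(row["_depths"])))
                                  if row["_depths"] else 0),
                "mean_alt_fraction": (round(float(np.mean(row["_afs"])), 2)
                                      if row["_afs"] else 0.0),
                "n_substitutions": row["substitution"],
                "pct_substitutions": percent(row["substitution"], n),
                "n_double_substitutions": row["double_substitution"],
                "pct_double_substitutions": percent(row["double_substitution"], n),
                "n_short_indels": row["short_indel"],
                "pct_short_indels": percent(row["short_indel"], n),
            }
        )
    df = pd.DataFrame(out).set_index("region")

    if coding_territory_mbp is not None:
        per_sample = {}
        for rec in tallied:
            if _REGION_BUCKET[rec.region] == "coding":
                per_sample[rec.sample_id] = per_sample.get(rec.sample_id, 0) + 1
        burdens = [n / coding_territory_mbp for n in per_sample.values()]
        df.attrs["burden_per_sample"] = {
            s: n / coding_territory_mbp for s, n in sorted(per_sample.items())
        }
        df.attrs["mean_burden_per_mbp"] = (
            float(np.mean(burdens)) if burdens else 0.0
        )
    return df


def mutation_burden(n_coding_mutations: int, coding_territory_mbp: float) -> float:
    """Mutations per Mbp of coding territory."""
    if coding_territory_mbp <= 0:
        raise ValueError("coding_territory_mbp must be > 0")
    return n_coding_mutations / coding_territory_mbp


def fisher_exact(table) -> tuple:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p)`` with the sample odds ratio (a*d)/(b*c),
    infinite when b*c == 0, and the exact two-sided p obtained by summing
    hypergeometric probabilities no larger than the observed table's.
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("cells must be nonnegative")
    if sum(cells) == 0:
        raise ValueError("all-zero table")
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
        if a * d == 0 and b * c == 0:
            odds = float("nan")
    else:
        odds = (a * d) / (b * c)
    _or, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)
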