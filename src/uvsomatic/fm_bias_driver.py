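"""Functional-mutation-bias driver test per gene-region.

For every gene-region with mutations, the observed arithmetic mean of the
mutations' functional-impact scores is compared against a resampling null:
each null draw places the same number of mutations on the region's scored
position-allele pairs, sampled *without* replacement with probability
proportional to the cohort-wide frequency of each pair's trinucleotide
mutation channel (so the null respects the cohort's mutational signature).
Empirical p-values use a +1 pseudocount and an inclusive tie rule;
Benjamini-Hochberg correction runs separately within each region class
(CDS, 5'UTR, 3'UTR, intron), and genes are tiered at q < 0.025
(significant) and q < 0.01 (highly significant).

This is a deliberately simplified functional-bias test in the mold of
element-level driver-discovery tools: arithmetic-mean statistic,
signature-complement resampling, and a max-over-window rule
(``max_consecutive``) for indels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .gene_annotation import AnnotationParams, RegionClass, classify_region
from .mutation_classes import context_index_of
from .recurrence_hotspots import _GENE_REGION_OF

REGION_CLASSES = ("CODING", "UTR5", "UTR3", "INTRON")


@dataclass
class FMBiasParams:
    n_iterations: int = 1000
    max_consecutive: int = 7
    seed: int = 0
    q_significant: float = 0.025
    q_highly: float = 0.01

    def __post_init__(self):
        if self.n_iterations < 100:
            raise ValueError("n_iterations must be >= 100")
        if self.max_consecutive < 1:
            raise ValueError("max_consecutive must be >= 1")


class ScoreTrack:
    """Per-position, per-alternate-allele functional scores."""

    def __init__(self, df: pd.DataFrame):
        df = df[["chrom", "pos", "alt", "score"]].copy()
        if (df["score"] < 0).any() or not np.isfinite(df["score"]).all():
            raise ValueError("scores must be finite and nonnegative")
        self.df = df.reset_index(drop=True)
        self._scores = {}
        self._by_pos = {}
        for c, p, a, s in zip(df["chrom"], df["pos"], df["alt"], df["score"]):
            key = (c, int(p), a)
            self._scores[key] = float(s)
            self._by_pos.setdefault((c, int(p)), []).append(float(s))

    def __len__(self):
        return len(self.df)

    @classmethod
    def from_tsv(cls, path) -> "ScoreTrack":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.8g")

    def score_of(self, chrom, pos, alt) -> float:
        try:
            return self._scores[(chrom, int(pos), alt)]
        except KeyError:
            raise ValueError(f"score gap at {chrom}:{pos} {alt}") from None

    def position_scores(self, chrom, pos):
        """Scores of every scored alternate at one position (may be empty)."""
        return self._by_pos.get((chrom, int(pos)), [])


@dataclass
class RegionPairs:
    """Scored (position, alt) pairs of one gene-region with their channels."""

    gene_id: str
    region: str
    chrom: str
    positions: np.ndarray
    alts: np.ndarray
    scores: np.ndarray
    channels: np.ndarray


@dataclass
class FMBiasResult:
    gene_id: str
    region: str
    n_mutations: int
    observed_mean: float
    p_value: float
    q_value: float = None
    tier: str = "none"


def build_region_tables(track: ScoreTrack, models, reference,
                        params: AnnotationParams = None) -> dict:
    """Map every scored pair to its (gene, region-class) bucket."""
    params = params or AnnotationParams()
    df = track.df
    # classify each unique position once
    classes = {}
    for chrom, pos in {(c, int(p)) for c, p in zip(df["chrom"], df["pos"])}:
        classes[(chrom, pos)] = classify_region(chrom, pos, models, params)
    buckets = {}
    for chrom, pos, alt, score in zip(df["chrom"], df["pos"], df["alt"],
                                      df["score"]):
        pos = int(pos)
        region_cls, gene = classes[(chrom, pos)]
        region = _GENE_REGION_OF.get(region_cls)
        if region is None or gene is None:
            continue
        ref = reference.base(chrom, pos)
        if ref == alt:
            continue
        five = reference.base(chrom, pos - 1)
        three = reference.base(chrom, pos + 1)
        chan = context_index_of(five, ref, alt, three)
        buckets.setdefault((gene, region), []).append(
            (pos, alt, float(score), chan, chrom)
        )
    out = {}
    for key, rows in buckets.items():
        rows.sort()
        out[key] = RegionPairs(
            gene_id=key[0], region=key[1], chrom=rows[0][4],
            positions=np.array([r[0] for r in rows]),
            alts=np.array([r[1] for r in rows]),
            scores=np.array([r[2] for r in rows]),
            channels=np.array([r[3] for r in rows]),
        )
    return out


# ---------------------------------------------------------------------------
# Observed statistic
# ---------------------------------------------------------------------------

def _mutation_score(rec, track: ScoreTrack, params: FMBiasParams) -> float:
    if rec.mtype == "SNV":
        return track.score_of(rec.chrom, rec.start, rec.alt)
    if len(rec.ref) == len(rec.alt):  # DBS / multi-substitution
        vals = []
        for i in range(len(rec.ref)):
            try:
                vals.append(track.score_of(rec.chrom, rec.start + i,
                                           rec.alt[i]))
            except ValueError:
                continue  # base outside the scored territory
        if not vals:
            raise ValueError(f"score gap at {rec.chrom}:{rec.start} (DBS)")
        return max(vals)
    # indel: max score over max_consecutive positions from the start
    vals = []
    for pos in range(rec.start, rec.start + params.max_consecutive):
        vals.extend(track.position_scores(rec.chrom, pos))
    if not vals:
        raise ValueError(f"score gap at {rec.chrom}:{rec.start} (indel)")
    return max(vals)


def observed_statistic(mutations, track: ScoreTrack,
                       params: FMBiasParams = None) -> float:
    """Arithmetic mean of per-mutation functional scores."""
    params = params or FMBiasParams()
    if not mutations:
        raise ValueError("no mutations in region")
    return float(np.mean([_mutation_score(m, track, params)
                          for m in mutations]))


# ---------------------------------------------------------------------------
# Null distribution
# ---------------------------------------------------------------------------

def null_distribution(pairs: RegionPairs, n_mut: int,
                      context_probs: np.ndarray,
                      params: FMBiasParams = None,
                      rng: np.random.Generator = None) -> np.ndarray:
    """Signature-weighted resampling null of the mean score.

    Each draw samples ``n_mut`` pairs without replacement with probability
    proportional to the cohort channel frequency of each pair's
    trinucleotide change (Gumbel top-k); pairs on zero-frequency channels
    are unsampleable.
    """
    params = params or FMBiasParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    w = np.asarray(context_probs, dtype=float)[pairs.channels]
    n_pos = int((w > 0).sum())
    if n_pos == 0:
        raise ValueError(
            f"{pairs.gene_id}/{pairs.region}: all channel probabilities zero"
        )
    if n_pos < n_mut:
        raise ValueError(
            f"{pairs.gene_id}/{pairs.region}: only {n_pos} sampleable pairs "
            f"for {n_mut} mutations"
        )
    with np.errstate(divide="ignore"):
        logw = np.log(w)
    gumbel = rng.gumbel(size=(params.n_iterations, w.size))
    keys = logw[None, :] + gumbel
    top = np.argpartition(-keys, n_mut - 1, axis=1)[:, :n_mut]
    return pairs.scores[top].mean(axis=1)


# ---------------------------------------------------------------------------
# The test
# ---------------------------------------------------------------------------

def group_mutations_by_region(records) -> dict:
    groups = {}
    for rec in records:
        region = _GENE_REGION_OF.get(rec.region)
        if region is None or rec.gene_id is None:
            continue
        if rec.region is RegionClass.SPLICE_SITE:
            continue  # splice pairs are intronic, outside the scored CDS set
        groups.setdefault((rec.gene_id, region), []).append(rec)
    return groups


def fm_bias_test(records, track: ScoreTrack, region_tables: dict,
                 context_probs: np.ndarray,
                 params: FMBiasParams = None) -> list:
    """Run the FM-bias test over every mutated, scored gene-region."""
    params = params or FMBiasParams()
    groups = group_mutations_by_region(records)
    results = []
    seeds = np.random.SeedSequence(params.seed)
    keys = sorted(k for k in groups if k in region_tables)
    children = seeds.spawn(len(keys))
    for key, child in zip(keys, children):
        muts = groups[key]
        pairs = region_tables[key]
        obs = observed_statistic(muts, track, params)
        rng = np.random.default_rng(child)
        null = null_distribution(pairs, len(muts), context_probs, params, rng)
        p = (1 + int((null >= obs).sum())) / (1 + params.n_iterations)
        results.append(
            FMBiasResult(gene_id=key[0], region=key[1],
                         n_mutations=len(muts), observed_mean=obs, p_value=p)
        )
    assign_q_values(results, params)
    return results


def assign_q_values(results, params: FMBiasParams = None):
    """BH within each region class; tier by q thresholds."""
    params = params or FMBiasParams()
    for region in REGION_CLASSES:
        sub = [r for r in results if r.region == region]
        if not sub:
            continue
        _rej, q, _a, _b = multipletests(
            [r.p_value for r in sub], method="fdr_bh"
        )
        for r, qv in zip(sub, q):
            r.q_value = float(qv)
            if qv < params.q_highly:
                r.tier = "highly_significant"
            elif qv < params.q_significant:
                r.tier = "significant"
            else:
                r.tier = "none"
    return results


def results_frame(results) -> pd.DataFrame:
    rows = [
        {"gene": r.gene_id, "region": r.region, "n_mutations": r.n_mutations,
         "observed_mean": r.observed_mean, "p_value": r.p_value,
         "q_value": r.q_value, "tier": r.tier}
        for r in sorted(results, key=lambda r: (r.region, r.p_value, r.gene_id))
    ]
    return pd.DataFrame(rows, columns=["gene", "region", "n_mutations",
                                       "observed_mean", "p_value",
                                       "q_value", "tier"])
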