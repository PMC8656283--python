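"""Seeded generator for everything the pipeline consumes.

Emulates a UV-driven 27-sample tumor/normal exome cohort: a compact
genome with multi-exon genes on both strands, per-sample mutation loads
drawn from a lognormal, single-base substitutions placed according to a
UV-dominant two-signature mixture (C>T at dipyrimidines, with one
alkylation-dominant sample and two near-empty samples), CC>TT double
substitutions emitted as adjacent SNV calls, short indels at
low-complexity runs, planted recurrence hotspots, planted high-score
driver regions, spiked filter-failing artifacts and germline/panel sites,
and chromosome-arm copy-number changes in MLPA probe signals.  Every
output is a deterministic function of the seed, and machine-readable
truth tables accompany each planted feature.

Scale note: the genome and per-region territories are orders of magnitude
smaller than a real exome while per-sample mutation counts match the
emulated cohort, so the background recurrence density is far higher than
in real data; truth-closure tests therefore assert containment/recall of
planted features rather than exact background counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fm_bias_driver import ScoreTrack
from .gene_annotation import AnnotationParams, RegionClass
from .io_formats import GeneModelSet, Reference, Transcript, revcomp
from .mlpa_copynumber import MLPAProbeSet, Probe
from .signature_fitting import uv_alkylation_signatures

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in _STOPS
]

# region codes for the painted class array (priority = numeric order)
_R_CODING, _R_SPLICE, _R_UTR5, _R_UTR3, _R_INTRON, _R_DEEP, _R_INTER = range(7)
_CODE_TO_REGION = {
    _R_CODING: RegionClass.CODING,
    _R_SPLICE: RegionClass.SPLICE_SITE,
    _R_UTR5: RegionClass.UTR5,
    _R_UTR3: RegionClass.UTR3,
    _R_INTRON: RegionClass.INTRON,
    _R_DEEP: RegionClass.INTRON_DEEP,
    _R_INTER: RegionClass.INTERGENIC,
}
_REGION_NAME_TO_CODE = {"CODING": _R_CODING, "UTR5": _R_UTR5,
                        "UTR3": _R_UTR3, "INTRON": _R_INTRON}


@dataclass
class PlantedHotspot:
    region: str  # CODING | UTR5 | UTR3 | INTRON
    n_carriers: int
    width: int = 1  # 1 or 2 adjacent positions


@dataclass
class PlantedDriver:
    region: str
    n_carriers: int
    high_score: float = 0.92


@dataclass
class PlantedCNA:
    arm: str  # "9p" | "9q"
    copies: int  # 1 = single-copy loss, 3 = single-copy gain
    n_samples: int = 2


@dataclass
class SimulationConfig:
    """Study conditions of the emulated cohort (defaults are the point)."""

    seed: int = 0
    n_samples: int = 27
    n_genes: int = 120
    genome_length: int = 900_000
    chrom: str = "chr1"
    # per-sample mutation count: lognormal, mean ~1.8k -> cohort ~50k
    lognorm_mu: float = 7.45
    lognorm_sigma: float = 0.35
    n_near_empty: int = 2  # sparsely mutated samples, excluded from signatures
    near_empty_count: int = 10
    n_alkyl_dominant: int = 1
    uv_weight_mean: float = 0.72  # cohort-mean UV signature weight
    uv_weight_conc: float = 25.0  # beta concentration of per-sample weights
    alkyl_dominant_uv_weight: float = 0.35
    dbs_fraction: float = 0.037
    indel_fraction: float = 0.018
    planted_hotspots: list = field(default_factory=lambda: [
        PlantedHotspot("UTR3", 8, 2),
        PlantedHotspot("UTR5", 5, 2),
        PlantedHotspot("UTR5", 4, 1),
        PlantedHotspot("CODING", 5, 1),
        PlantedHotspot("CODING", 3, 1),
    ])
    planted_drivers: list = field(default_factory=lambda: [
        PlantedDriver("UTR3", 8),
        PlantedDriver("UTR5", 6),
        PlantedDriver("CODING", 6),
    ])
    planted_cnas: list = field(default_factory=lambda: [
        PlantedCNA("9q", 1, 3),
        PlantedCNA("9p", 3, 2),
    ])
    n_artifacts_per_reason: int = 20
    n_germline_sites: int = 30
    n_pon_sites: int = 30
    # read-support model: exome-like depth, mid-range allele fractions
    depth_mean: float = 180.0
    depth_dispersion: float = 12.0
    af_beta_a: float = 3.5
    af_beta_b: float = 6.5
    # coverage emulation windows
    intron_prox_window: int = 100
    utr3_prox_window: int = 100
    flank_window: int = 150
    splice_window: int = 2
    # functional-score background (beta) and MLPA noise
    score_bg_a: float = 1.2
    score_bg_b: float = 4.0
    mlpa_noise_sigma: float = 0.05

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for f in (self.dbs_fraction, self.indel_fraction):
            if not 0 <= f <= 1:
                raise ValueError("type fractions must lie in [0, 1]")
        if self.dbs_fraction + self.indel_fraction > 1:
            raise ValueError("type fractions must sum to <= 1")

    def sample_ids(self):
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    def annotation_params(self) -> AnnotationParams:
        return AnnotationParams(
            splice_window=self.splice_window,
            intron_prox_window=self.intron_prox_window,
            utr3_prox_window=self.utr3_prox_window,
        )


@dataclass
class TruthTables:
    hotspots: pd.DataFrame = None
    drivers: pd.DataFrame = None
    cnas: pd.DataFrame = None
    signatures: pd.DataFrame = None
    artifacts: pd.DataFrame = None
    event_counts: pd.DataFrame = None

    def write(self, outdir):
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("hotspots", "drivers", "cnas", "signatures",
                     "artifacts", "event_counts"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(8)
    return np.random.default_rng(children[stage])


# ---------------------------------------------------------------------------
# Genome + gene models
# ---------------------------------------------------------------------------

def _random_bases(rng, n) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def _gene_segments(rng):
    """Transcription-order (type, sequence) segments of one gene."""
    u5 = rng.integers(60, 151)
    u3 = rng.integers(150, 301)
    n_chunks = int(rng.integers(2, 5))
    n_codons = int(rng.integers(100, 301))
    codons = (
        ["ATG"]
        + [
            _NONSTOP_CODONS[i]
            for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
        ]
        + [_STOPS[rng.integers(0, 3)]]
    )
    cds_seq = "".join(codons)
    cuts = sorted(rng.choice(
        np.arange(1, n_codons), size=n_chunks - 1, replace=False
    )) if n_chunks > 1 else []
    chunk_bounds = [0] + [3 * c for c in cuts] + [len(cds_seq)]
    segments = [("utr5", _random_bases(rng, u5))]
    for i in range(n_chunks):
        segments.append(("cds", cds_seq[chunk_bounds[i]:chunk_bounds[i + 1]]))
        if i < n_chunks - 1:
            segments.append(("intron", _random_bases(rng, int(rng.integers(250, 501)))))
    segments.append(("utr3", _random_bases(rng, u3)))
    return segments


def generate_genome(config: SimulationConfig):
    """Deterministic genome and gene models; both strands represented."""
    rng = _stage_rng(config, 0)
    chrom = config.chrom
    pieces = []  # (start, seq) 1-based
    transcripts = {}
    cursor = 1 + config.flank_window
    for i in range(config.n_genes):
        gap = int(rng.integers(500, 1201))
        strand = "+" if rng.random() < 0.5 else "-"
        segments = _gene_segments(rng)
        gene_len = sum(len(s) for _t, s in segments)
        start = cursor + gap
        end = start + gene_len - 1
        if end + config.flank_window + 1 > config.genome_length:
            raise ValueError(
                f"genome_length {config.genome_length} too small for "
                f"{config.n_genes} genes (gene {i} would end at {end})"
            )
        tx_seq = "".join(s for _t, s in segments)
        genomic_seq = tx_seq if strand == "+" else revcomp(tx_seq)
        pieces.append((start, genomic_seq))

        # map transcription-order segments onto genomic intervals
        ivs = {"utr5": [], "cds": [], "intron": [], "utr3": []}
        off = 0
        for typ, seq in segments:
            L = len(seq)
            if strand == "+":
                s, e = start + off, start + off + L - 1
            else:
                s = start + (gene_len - off - L)
                e = start + (gene_len - off - 1)
            ivs[typ].append((s, e))
            off += L
        exonic = sorted(ivs["utr5"] + ivs["cds"] + ivs["utr3"])
        exons = []
        for s, e in exonic:
            if exons and s == exons[-1][1] + 1:
                exons[-1] = (exons[-1][0], e)
            else:
                exons.append((s, e))
        gid = f"G{i + 1:03d}"
        transcripts[f"TX{i + 1:03d}"] = Transcript(
            transcript_id=f"TX{i + 1:03d}", gene_id=gid,
            gene_name=f"GENE{i + 1:03d}", chrom=chrom, strand=strand,
            exons=exons, cds=sorted(ivs["cds"]),
            utr5=sorted(ivs["utr5"]), utr3=sorted(ivs["utr3"]),
        )
        cursor = end
    # fill the whole contig with random background, then paste genes
    seq = np.array(list(_random_bases(rng, config.genome_length)))
    for start, gseq in pieces:
        seq[start - 1 : start - 1 + len(gseq)] = list(gseq)
    reference = Reference({chrom: "".join(seq)})
    return reference, GeneModelSet(transcripts=transcripts)


# ---------------------------------------------------------------------------
# Region painting + coverage mask (vectorized companions to gene_annotation)
# ---------------------------------------------------------------------------

def paint_region_classes(config: SimulationConfig,
                         models: GeneModelSet) -> np.ndarray:
    """Per-base region code array (min-priority across overlapping genes)."""
    L = config.genome_length
    arr = np.full(L + 1, _R_INTER, dtype=np.int8)  # index 1..L
    gene_arr = np.zeros(L + 1, dtype=np.int32)  # 0 = no gene

    def paint(lo, hi, code, gene_no):
        lo, hi = max(1, lo), min(L, hi)
        if lo > hi:
            return
        sl = slice(lo, hi + 1)
        mask = arr[sl] > code
        arr[sl] = np.where(mask, code, arr[sl])
        gene_arr[sl] = np.where(mask, gene_no, gene_arr[sl])

    gene_ids = models.gene_ids()
    for gno, gid in enumerate(gene_ids, start=1):
        tx = models.canonical(gid)
        for s, e in tx.utr5:
            paint(s, e, _R_UTR5, gno)
        for s, e in tx.utr3:
            paint(s, e, _R_UTR3, gno)
        for s, e in tx.cds:
            paint(s, e, _R_CODING, gno)
        for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
            i_lo, i_hi = e1 + 1, s2 - 1
            paint(i_lo, i_hi, _R_DEEP, gno)
            w = config.intron_prox_window
            paint(i_lo, min(i_lo + w - 1, i_hi), _R_INTRON, gno)
            paint(max(i_hi - w + 1, i_lo), i_hi, _R_INTRON, gno)
            sw = config.splice_window
            paint(i_lo, min(i_lo + sw - 1, i_hi), _R_SPLICE, gno)
            paint(max(i_hi - sw + 1, i_lo), i_hi, _R_SPLICE, gno)
    return arr, gene_arr, gene_ids


def covered_mask(config: SimulationConfig, models: GeneModelSet) -> np.ndarray:
    """Exome-capture emulation: exons +- intron window, proximal 3'UTR,
    UTR5, and short intergenic flanks around each gene."""
    L = config.genome_length
    mask = np.zeros(L + 1, dtype=bool)

    def cover(lo, hi):
        mask[max(2, lo): min(L - 1, hi) + 1] = True

    for gid in models.gene_ids():
        tx = models.canonical(gid)
        for s, e in tx.cds:
            cover(s, e)
        for s, e in tx.utr5:
            cover(s, e)
        for s, e in tx.utr3:
            if tx.strand == "+":
                cover(s, min(e, s + config.utr3_prox_window - 1))
            else:
                cover(max(s, e - config.utr3_prox_window + 1), e)
        for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
            i_lo, i_hi = e1 + 1, s2 - 1
            w = config.intron_prox_window
            cover(i_lo, min(i_lo + w - 1, i_hi))
            cover(max(i_hi - w + 1, i_lo), i_hi)
        cover(tx.start - config.flank_window, tx.start - 1)
        cover(tx.end + 1, tx.end + config.flank_window)
    return mask


_CLS_MAP = np.full((4, 4), -1, dtype=np.int64)
for _pair, _idx in (((1, 0), 0), ((1, 2), 1), ((1, 3), 2),
                    ((3, 0), 3), ((3, 1), 4), ((3, 2), 5)):
    _CLS_MAP[_pair] = _idx


def pair_channels(codes: np.ndarray, positions: np.ndarray) -> tuple:
    """(alt codes, channels) for the 3 alternates of each 1-based position.

    Vectorized twin of :func:`mutation_classes.context_index_of`.
    """
    ref = codes[positions - 1]
    five = codes[positions - 2]
    three = codes[positions]
    alts = np.empty((positions.size, 3), dtype=np.int64)
    for k in range(3):
        alts[:, k] = (ref + 1 + k) % 4
    is_pur = (ref == 0) | (ref == 2)
    ref_n = np.where(is_pur, 3 - ref, ref)
    five_n = np.where(is_pur, 3 - three, five)
    three_n = np.where(is_pur, 3 - five, three)
    channels = np.empty_like(alts)
    for k in range(3):
        alt_n = np.where(is_pur, 3 - alts[:, k], alts[:, k])
        channels[:, k] = _CLS_MAP[ref_n, alt_n] * 16 + five_n * 4 + three_n
    return alts, channels


# ---------------------------------------------------------------------------
# Score track
# ---------------------------------------------------------------------------

def simulate_score_track(config: SimulationConfig, reference: Reference,
                         models: GeneModelSet):
    """Background functional scores plus planted high-score driver regions.

    Returns (ScoreTrack, driver truth records); driver mutations are later
    placed at the planted high-score positions by :func:`simulate_cohort`.
    """
    rng = _stage_rng(config, 1)
    region_arr, gene_arr, gene_ids = paint_region_classes(config, models)
    mask = covered_mask(config, models)
    codes = _encode(reference, config)

    idx = np.arange(config.genome_length + 1)
    in_gene = np.flatnonzero(
        mask & (idx >= 2) & (idx <= config.genome_length - 1)
        & np.isin(region_arr, [_R_CODING, _R_SPLICE, _R_UTR5, _R_UTR3,
                               _R_INTRON])
    )
    positions = in_gene.astype(np.int64)
    alts, _chan = pair_channels(codes, positions)
    n = positions.size
    scores = rng.beta(config.score_bg_a, config.score_bg_b, size=(n, 3))

    # plant drivers: distinct genes, top scores at chosen C/G positions
    used_genes = set()
    driver_rows = []
    base_at = codes[positions - 1]
    for d_i, driver in enumerate(config.planted_drivers):
        code = _REGION_NAME_TO_CODE[driver.region]
        cand = (
            (region_arr[positions] == code)
            & ((base_at == 1) | (base_at == 2))  # C or G: UV-type channel
        )
        genes_here = gene_arr[positions]
        ok_gene = None
        for gno in np.unique(genes_here[cand]):
            gid = gene_ids[gno - 1]
            if gid in used_genes or gno == 0:
                continue
            idx = np.flatnonzero(cand & (genes_here == gno))
            if idx.size >= driver.n_carriers:
                ok_gene = (gid, idx)
                break
        if ok_gene is None:
            raise ValueError(
                f"no gene with enough {driver.region} positions for driver"
            )
        gid, idx = ok_gene
        used_genes.add(gid)
        chosen = rng.choice(idx, size=driver.n_carriers, replace=False)
        scores[chosen, :] = driver.high_score + 0.07 * rng.random(
            (driver.n_carriers, 3)
        )
        for j, row in enumerate(chosen):
            driver_rows.append(
                {"gene": gid, "region": driver.region,
                 "pos": int(positions[row]),
                 "driver_index": d_i}
            )
    scores = np.clip(scores, 0.0, 1.0)

    alt_bases = np.array(list(BASES))[alts]
    df = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": np.repeat(positions, 3),
            "alt": alt_bases.ravel(),
            "score": scores.ravel(),
        }
    )
    truth = pd.DataFrame(driver_rows,
                         columns=["gene", "region", "pos", "driver_index"])
    return ScoreTrack(df), truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _encode(reference: Reference, config) -> np.ndarray:
    raw = np.frombuffer(
        reference.seq(config.chrom, 1, config.genome_length).encode(), np.uint8
    )
    codes = np.zeros(raw.size, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        codes[raw == b] = i
    return codes


def _weighted_topk(rng, logw, k, n_candidates):
    """Indices of a weighted sample without replacement (Gumbel top-k),
    returned in draw-preference order, ``n_candidates`` of them."""
    keys = logw + rng.gumbel(size=logw.size)
    n = min(n_candidates, logw.size)
    idx = np.argpartition(-keys, n - 1)[:n]
    return idx[np.argsort(-keys[idx])]


def simulate_cohort(config: SimulationConfig, reference: Reference,
                    models: GeneModelSet, driver_truth: pd.DataFrame = None):
    """Per-sample somatic calls with planted structure and truth tables.

    Returns (calls dict sample_id -> list of row dicts, TruthTables).
    Rows are VCF-ready: CHROM/POS/REF/ALT plus tumor/normal AD counts.
    A double substitution is emitted as two adjacent SNV rows so that the
    merging stage reconstructs it, as a caller would emit it.
    """
    rng = _stage_rng(config, 2)
    chrom = config.chrom
    codes = _encode(reference, config)
    region_arr, gene_arr, gene_ids = paint_region_classes(config, models)
    mask = covered_mask(config, models)
    positions = np.flatnonzero(mask)
    positions = positions[(positions >= 2)
                          & (positions <= config.genome_length - 1)]
    alts, chans = pair_channels(codes, positions)

    sigs = uv_alkylation_signatures()
    uv_row, alk_row = sigs.matrix

    # channel -> probability is spread uniformly over that channel's pairs
    chan_count = np.bincount(chans.ravel(), minlength=96).astype(float)
    inv_count = np.zeros(96)
    nz = chan_count > 0
    inv_count[nz] = 1.0 / chan_count[nz]

    ids = config.sample_ids()
    order = rng.permutation(config.n_samples)
    near_empty = [ids[i] for i in order[: config.n_near_empty]]
    alkyl = [ids[i] for i in order[
        config.n_near_empty : config.n_near_empty + config.n_alkyl_dominant]]

    mu = config.uv_weight_mean
    conc = config.uv_weight_conc
    uv_w = {}
    for sid in ids:
        if sid in alkyl:
            uv_w[sid] = config.alkyl_dominant_uv_weight
        else:
            uv_w[sid] = float(rng.beta(mu * conc, (1 - mu) * conc))

    totals = {}
    for sid in ids:
        if sid in near_empty:
            totals[sid] = int(config.near_empty_count)
        else:
            totals[sid] = int(round(rng.lognormal(config.lognorm_mu,
                                                  config.lognorm_sigma)))

    # --- planted hotspots: positions + carriers chosen cohort-wide ---
    eligible = [s for s in ids if s not in near_empty]
    base_at = codes[positions - 1]
    hotspot_rows = []
    planted = {sid: [] for sid in ids}  # per-sample (pos, ref, alt) SNV plants
    occupied_plants = set()
    for h_i, hs in enumerate(config.planted_hotspots):
        code = _REGION_NAME_TO_CODE[hs.region]
        cg = (base_at == 1) | (base_at == 2)
        cand = np.flatnonzero((region_arr[positions] == code) & cg)
        rng.shuffle(cand)
        chosen = None
        for row in cand:
            p = int(positions[row])
            span = [p, p + 1] if hs.width == 2 else [p]
            if any(q in occupied_plants or (q - 1) in occupied_plants
                   or (q + 1) in occupied_plants for q in span):
                continue
            if hs.width == 2:
                # need an identical-base dinucleotide (CC or GG) for CC>TT
                if codes[p] != codes[p - 1] or region_arr[p + 1] != code:
                    continue
                if not mask[p + 1]:
                    continue
            chosen = span
            break
        if chosen is None:
            raise ValueError(f"no placement for planted hotspot {hs}")
        if hs.n_carriers > len(eligible):
            raise ValueError(
                f"planted hotspot needs {hs.n_carriers} carriers but only "
                f"{len(eligible)} non-near-empty samples exist"
            )
        occupied_plants.update(chosen)
        carriers = [eligible[i] for i in
                    rng.choice(len(eligible), size=hs.n_carriers,
                               replace=False)]
        for j, sid in enumerate(carriers):
            ref_b = BASES[codes[chosen[0] - 1]]
            alt_b = "T" if ref_b == "C" else "A"
            if hs.width == 2 and j == 0:
                # one carrier gets the full CC>TT (two adjacent rows)
                planted[sid].append((chosen[0], ref_b, alt_b))
                planted[sid].append((chosen[1], ref_b, alt_b))
            elif hs.width == 2:
                p = chosen[j % 2]
                planted[sid].append((p, ref_b, alt_b))
            else:
                planted[sid].append((chosen[0], ref_b, alt_b))
        gid = gene_ids[gene_arr[chosen[0]] - 1] if gene_arr[chosen[0]] else ""
        hotspot_rows.append(
            {"hotspot_index": h_i, "chrom": chrom,
             "start": chosen[0], "end": chosen[-1],
             "region": hs.region, "gene": gid,
             "n_carriers": hs.n_carriers,
             "carriers": ",".join(sorted(carriers))}
        )

    # --- planted drivers: carriers placed on the high-score positions ---
    driver_assign_rows = []
    if driver_truth is not None and len(driver_truth):
        for d_i, sub in driver_truth.groupby("driver_index"):
            pos_list = [int(p) for p in sub["pos"]]
            carriers = [eligible[i] for i in
                        rng.choice(len(eligible), size=len(pos_list),
                                   replace=False)]
            for p, sid in zip(pos_list, carriers):
                if p in occupied_plants:
                    continue
                ref_b = BASES[codes[p - 1]]
                alt_b = "T" if ref_b == "C" else "A"
                planted[sid].append((p, ref_b, alt_b))
                occupied_plants.add(p)
                driver_assign_rows.append(
                    {"gene": sub["gene"].iloc[0],
                     "region": sub["region"].iloc[0],
                     "pos": p, "sample": sid}
                )

    # --- per-sample random placement ---
    # CC/GG dinucleotide starts, both positions covered
    p_all = np.arange(1, config.genome_length)
    cc = (codes[p_all - 1] == codes[p_all]) & (
        (codes[p_all - 1] == 1) | (codes[p_all - 1] == 2)
    ) & mask[p_all] & mask[p_all + 1] & (p_all >= 2)
    dinuc_starts = p_all[cc]

    # homopolymer-run starts (>=3 identical bases) for low-complexity indels
    run3 = (codes[p_all - 1] == codes[p_all]) & (
        codes[p_all] == codes[np.minimum(p_all + 1, config.genome_length) - 1]
    ) & mask[p_all - 1] & mask[p_all] & (p_all >= 3)
    run_starts = p_all[run3]

    calls = {sid: [] for sid in ids}
    truth_sig_rows = []
    count_rows = []
    for sid in ids:
        n_total = totals[sid]
        n_dbs = int(round(n_total * config.dbs_fraction))
        n_ind = int(round(n_total * config.indel_fraction))
        n_snv = n_total - n_dbs - n_ind
        occupied = set()
        snv_pos = set()

        def blocked(p, guard_snv=False):
            if p in occupied:
                return True
            if guard_snv and ((p - 1) in snv_pos or (p + 1) in snv_pos):
                return True
            return False

        events = []  # (pos, ref, alt)

        for p, ref_b, alt_b in planted[sid]:
            events.append((p, ref_b, alt_b))
            occupied.add(p)
            snv_pos.add(p)

        # double substitutions (CC>TT / GG>AA) as two adjacent rows
        if n_dbs and dinuc_starts.size:
            picks = rng.permutation(dinuc_starts)[: n_dbs * 4 + 16]
            placed = 0
            for p in picks:
                p = int(p)
                if placed >= n_dbs:
                    break
                if any(blocked(q) for q in (p - 1, p, p + 1, p + 2)):
                    continue
                ref_b = BASES[codes[p - 1]]
                alt_b = "T" if ref_b == "C" else "A"
                events.append((p, ref_b, alt_b))
                events.append((p + 1, ref_b, alt_b))
                occupied.update((p, p + 1))
                snv_pos.update((p, p + 1))
                placed += 1

        # short indels at low-complexity runs
        if n_ind and run_starts.size:
            picks = rng.permutation(run_starts)[: n_ind * 4 + 16]
            placed = 0
            for p in picks:
                p = int(p)
                if placed >= n_ind:
                    break
                anchor = p - 1
                L = int(rng.integers(1, 4))
                span = range(anchor, anchor + L + 1)
                if any(blocked(q) for q in span):
                    continue
                run_b = BASES[codes[p - 1]]
                anchor_b = BASES[codes[anchor - 1]]
                if rng.random() < 2 / 3:  # deletion
                    ref_a, alt_a = anchor_b + run_b * L, anchor_b
                else:
                    ref_a, alt_a = anchor_b, anchor_b + run_b * L
                events.append((anchor, ref_a, alt_a))
                occupied.update(span)
                placed += 1

        # signature-mixture SNVs
        if n_snv:
            p96 = uv_w[sid] * uv_row + (1 - uv_w[sid]) * alk_row
            w_pair = (p96 * inv_count)[chans]  # (N, 3)
            w_pos = w_pair.sum(axis=1)
            with np.errstate(divide="ignore"):
                logw = np.log(w_pos)
            ranked = _weighted_topk(rng, logw, n_snv, n_snv + 400)
            placed = 0
            chosen_rows = []
            for row in ranked:
                p = int(positions[row])
                if placed >= n_snv:
                    break
                if blocked(p, guard_snv=True):
                    continue
                chosen_rows.append(row)
                occupied.add(p)
                snv_pos.add(p)
                placed += 1
            if placed < n_snv:
                logger.warning("%s: placed %d/%d SNVs (genome saturated)",
                               sid, placed, n_snv)
            rows = np.array(chosen_rows, dtype=int)
            if rows.size:
                w = w_pair[rows]
                w = w / w.sum(axis=1, keepdims=True)
                u = rng.random(rows.size)
                k = np.minimum(
                    (u[:, None] > np.cumsum(w, axis=1)).sum(axis=1), 2
                )
                for row, kk in zip(rows, k):
                    p = int(positions[row])
                    events.append((p, BASES[codes[p - 1]],
                                   BASES[alts[row, kk]]))

        truth_sig_rows.append(
            {"sample": sid, "uv_weight": uv_w[sid],
             "alkyl_weight": 1 - uv_w[sid], "n_mutations": n_total,
             "near_empty": sid in near_empty,
             "alkyl_dominant": sid in alkyl}
        )
        count_rows.append(
            {"sample": sid, "n_total": n_total, "n_snv": n_snv,
             "n_dbs": n_dbs, "n_indel": n_ind}
        )
        calls[sid] = [
            {"chrom": chrom, "pos": p, "ref": r, "alt": a}
            for p, r, a in sorted(events)
        ]

    # --- read support for true somatic events ---
    for sid in ids:
        for ev in calls[sid]:
            d_t = max(40, int(rng.negative_binomial(
                config.depth_dispersion,
                config.depth_dispersion / (config.depth_dispersion
                                           + config.depth_mean))))
            af = float(rng.beta(config.af_beta_a, config.af_beta_b))
            alt_t = max(5, int(round(af * d_t)))
            alt_t = min(alt_t, d_t)
            if alt_t / d_t < 0.05:
                alt_t = int(np.ceil(0.05 * d_t))
            d_n = max(40, int(rng.negative_binomial(
                config.depth_dispersion,
                config.depth_dispersion / (config.depth_dispersion
                                           + config.depth_mean))))
            if rng.random() < 0.12:
                cap = int((alt_t / d_t) * d_n / (5.0 * 1.2))
                alt_n = int(rng.integers(0, cap + 1)) if cap > 0 else 0
            else:
                alt_n = 0
            ev.update(tumor_alt=alt_t, tumor_depth=d_t,
                      normal_alt=alt_n, normal_depth=d_n)

    # --- spiked artifacts that must fail the somatic filters ---
    artifact_rows = []
    free = positions[~np.isin(positions, list(occupied_plants))]
    art_pos = rng.permutation(free)
    ap = iter(int(p) for p in art_pos)
    # spike positions must be unused cohort-wide: site lists are keyed by
    # (chrom, pos, ref, alt) and must not flag true calls of other samples
    taken_everywhere = {e["pos"] for rows in calls.values() for e in rows}

    def next_free(sid):
        while True:
            p = next(ap)
            if p not in taken_everywhere:
                taken_everywhere.add(p)
                return p

    for reason in ("low_support", "low_af", "low_ratio"):
        for _ in range(config.n_artifacts_per_reason):
            sid = ids[int(rng.integers(0, len(ids)))]
            p = next_free(sid)
            ref_b = BASES[codes[p - 1]]
            alt_b = BASES[(_CODE[ref_b] + 1 + int(rng.integers(0, 3))) % 4]
            if reason == "low_support":
                row = dict(tumor_alt=int(rng.integers(1, 5)), tumor_depth=150,
                           normal_alt=0, normal_depth=160)
            elif reason == "low_af":
                row = dict(tumor_alt=6, tumor_depth=200,
                           normal_alt=0, normal_depth=180)
            else:
                row = dict(tumor_alt=30, tumor_depth=150,  # AF 0.2
                           normal_alt=10, normal_depth=180)  # ratio 3.6
            calls[sid].append(
                {"chrom": chrom, "pos": p, "ref": ref_b, "alt": alt_b, **row}
            )
            artifact_rows.append(
                {"sample": sid, "chrom": chrom, "pos": p, "ref": ref_b,
                 "alt": alt_b, "reason": reason}
            )

    # --- germline / panel-of-normals sites (pass filters, flagged away) ---
    site_rows = []
    for kind, n_sites in (("germline", config.n_germline_sites),
                          ("pon", config.n_pon_sites)):
        for _ in range(n_sites):
            sid = ids[int(rng.integers(0, len(ids)))]
            p = next_free(sid)
            ref_b = BASES[codes[p - 1]]
            alt_b = BASES[(_CODE[ref_b] + 1 + int(rng.integers(0, 3))) % 4]
            calls[sid].append(
                {"chrom": chrom, "pos": p, "ref": ref_b, "alt": alt_b,
                 "tumor_alt": 40, "tumor_depth": 100,
                 "normal_alt": 0, "normal_depth": 120}
            )
            artifact_rows.append(
                {"sample": sid, "chrom": chrom, "pos": p, "ref": ref_b,
                 "alt": alt_b, "reason": kind}
            )

    for sid in ids:
        calls[sid].sort(key=lambda e: e["pos"])

    truth = TruthTables(
        hotspots=pd.DataFrame(hotspot_rows),
        drivers=pd.DataFrame(driver_assign_rows,
                             columns=["gene", "region", "pos", "sample"]),
        signatures=pd.DataFrame(truth_sig_rows),
        artifacts=pd.DataFrame(artifact_rows,
                               columns=["sample", "chrom", "pos", "ref",
                                        "alt", "reason"]),
        event_counts=pd.DataFrame(count_rows),
    )
    return calls, truth


# ---------------------------------------------------------------------------
# MLPA
# ---------------------------------------------------------------------------

CENTROMERE_9 = 43_000_000


def default_probe_set() -> MLPAProbeSet:
    """Chromosome-9 probe layout with distal controls."""
    probes = [
        Probe("P9P1", "chr9", 2_000_000, "9p-arm", False),
        Probe("P9P2", "chr9", 9_000_000, "9p-arm", False),
        Probe("P9P3", "chr9", 16_000_000, "9p-arm", False),
        Probe("P9P4", "chr9", 24_000_000, "9p-arm", False),
        Probe("P9P5", "chr9", 33_000_000, "9p-arm", False),
        Probe("JAK2_A", "chr9", 4_985_000, "JAK2", False),
        Probe("JAK2_B", "chr9", 5_090_000, "JAK2", False),
        Probe("PDL1_A", "chr9", 5_450_000, "PDL1", False),
        Probe("PDL2_A", "chr9", 5_510_000, "PDL2", False),
        Probe("P9Q1", "chr9", 70_000_000, "9q-arm", False),
        Probe("P9Q2", "chr9", 120_000_000, "9q-arm", False),
        Probe("PTCH1_A", "chr9", 95_440_000, "PTCH1", False),
        Probe("PTCH1_B", "chr9", 95_500_000, "PTCH1", False),
        Probe("D9_A", "chr9", 101_000_000, "9q-arm", False),
        Probe("D9_B", "chr9", 130_500_000, "9q-arm", False),
        Probe("CTRL1", "chr2", 50_000_000, "control", True),
        Probe("CTRL2", "chr3", 80_000_000, "control", True),
        Probe("CTRL3", "chr5", 60_000_000, "control", True),
        Probe("CTRL4", "chr7", 30_000_000, "control", True),
        Probe("CTRL5", "chr12", 40_000_000, "control", True),
    ]
    return MLPAProbeSet(probes)


def _probe_arm(probe: Probe) -> str:
    if probe.chrom != "chr9":
        return ""
    return "9p" if probe.pos < CENTROMERE_9 else "9q"


def simulate_mlpa(config: SimulationConfig, probes: MLPAProbeSet = None):
    """(tumor_signals, normal_signals, cna truth) with planted arm CNAs."""
    rng = _stage_rng(config, 3)
    probes = probes or default_probe_set()
    ids = config.sample_ids()
    base = {p.probe_id: float(rng.lognormal(np.log(1000), 0.25))
            for p in probes.probes}

    copy_state = {sid: {} for sid in ids}
    truth_rows = []
    for cna in config.planted_cnas:
        affected = [ids[i] for i in
                    rng.choice(len(ids), size=cna.n_samples, replace=False)]
        arm_probes = [p.probe_id for p in probes.probes
                      if not p.is_control and _probe_arm(p) == cna.arm]
        for sid in affected:
            for pid in arm_probes:
                copy_state[sid][pid] = cna.copies
            truth_rows.append(
                {"sample": sid, "arm": cna.arm, "copies": cna.copies,
                 "probes": ",".join(arm_probes)}
            )

    sigma = config.mlpa_noise_sigma
    tumor, normal = {}, {}
    for sid in ids:
        t, n = {}, {}
        for p in probes.probes:
            copies = 2 if p.is_control else copy_state[sid].get(p.probe_id, 2)
            noise_t = float(np.exp(rng.normal(0, sigma))) if sigma > 0 else 1.0
            noise_n = float(np.exp(rng.normal(0, sigma))) if sigma > 0 else 1.0
            t[p.probe_id] = base[p.probe_id] * (copies / 2.0) * noise_t
            n[p.probe_id] = base[p.probe_id] * noise_n
        tumor[sid], normal[sid] = t, n
    truth = pd.DataFrame(truth_rows,
                         columns=["sample", "arm", "copies", "probes"])
    return tumor, normal, truth


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={chrom},length={length}>
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{tumor}\t{normal}
"""


def write_sample_vcf(rows, chrom, chrom_length, sample_id, path):
    tumor, normal = f"{sample_id}_T", f"{sample_id}_N"
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(chrom=chrom, length=chrom_length,
                                   tumor=tumor, normal=normal))
        for r in rows:
            t_ref = r["tumor_depth"] - r["tumor_alt"]
            n_ref = r["normal_depth"] - r["normal_alt"]
            fh.write(
                f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t.\t"
                f"PASS\t.\tAD:DP\t"
                f"{t_ref},{r['tumor_alt']}:{r['tumor_depth']}\t"
                f"{n_ref},{r['normal_alt']}:{r['normal_depth']}\n"
            )


def generate_dataset(config: SimulationConfig, outdir):
    """Emit the full synthetic dataset + truth under one directory."""
    from pathlib import Path

    from .io_formats import write_fasta, write_site_list
    from .mlpa_copynumber import write_signal_table

    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)

    reference, models = generate_genome(config)
    track, driver_truth = simulate_score_track(config, reference, models)
    calls, truth = simulate_cohort(config, reference, models, driver_truth)
    probes = default_probe_set()
    mlpa_t, mlpa_n, cna_truth = simulate_mlpa(config, probes)
    truth.cnas = cna_truth

    write_fasta({config.chrom: reference.seq(config.chrom, 1,
                                             config.genome_length)},
                outdir / "genome.fa")
    write_gtf(models, outdir / "genes.gtf")
    for sid in config.sample_ids():
        write_sample_vcf(calls[sid], config.chrom, config.genome_length,
                         sid, outdir / "vcf" / f"{sid}.vcf")
    track.to_tsv(outdir / "score_track.tsv")
    uv_alkylation_signatures().to_tsv(outdir / "signatures.tsv")
    probes.to_tsv(outdir / "mlpa_probes.tsv")
    write_signal_table(mlpa_t, outdir / "mlpa_tumor.tsv")
    write_signal_table(mlpa_n, outdir / "mlpa_normal.tsv")

    art = truth.artifacts
    germ = art[art["reason"] == "germline"]
    pon = art[art["reason"] == "pon"]
    write_site_list(
        {(r.chrom, int(r.pos), r.ref, r.alt) for r in germ.itertuples()},
        outdir / "germline_sites.tsv")
    write_site_list(
        {(r.chrom, int(r.pos), r.ref, r.alt) for r in pon.itertuples()},
        outdir / "pon_sites.tsv")
    truth.write(outdir / "truth")
    return {"reference": reference, "models": models, "track": track,
            "calls": calls, "truth": truth, "probes": probes,
            "mlpa_tumor": mlpa_t, "mlpa_normal": mlpa_n, "outdir": outdir}


def write_gtf(models: GeneModelSet, path):
    with open(path, "w") as fh:
        for txid in sorted(models.transcripts):
            tx = models.transcripts[txid]
            attrs = (f'gene_id "{tx.gene_id}"; transcript_id "{txid}"; '
                     f'gene_name "{tx.gene_name}";')
            for s, e in tx.exons:
                fh.write(f"{tx.chrom}\tsim\texon\t{s}\t{e}\t.\t"
                         f"{tx.strand}\t.\t{attrs}\n")
            for s, e in tx.cds:
                fh.write(f"{tx.chrom}\tsim\tCDS\t{s}\t{e}\t.\t"
                         f"{tx.strand}\t0\t{attrs}\n")
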