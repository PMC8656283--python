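"""Shared fixtures: a handcrafted two-gene genome with known coordinates
and effects, and session-scoped synthetic datasets."""

import numpy as np
import pytest

from uvsomatic.io_formats import GeneModelSet, Reference, Transcript, revcomp
from uvsomatic.synthetic_data import (
    PlantedDriver,
    PlantedHotspot,
    SimulationConfig,
    generate_dataset,
)

# ---------------------------------------------------------------------------
# Handcrafted gene: designed so that textbook coordinates fall out exactly.
#
# Transcription-sense layout (identical for both strands):
#   5'UTR   60 nt   (c.-60 .. c.-1;  c.-5 and c.-4 are G G)
#   CDS#1   90 nt   (codons 1-30; codon 1 ATG, codon 2 CAA, codon 24 TCC)
#   intron 150 nt
#   CDS#2   90 nt   (codons 31-60; codon 60 TAA stop)
#   3'UTR  150 nt   (c.*142 and c.*143 are C C)
# ---------------------------------------------------------------------------

UTR5 = "A" * 50 + "CATGG" + "GG" + "AAC"          # 60 nt; offsets 55,56 = G,G
_CODONS = ["ATG", "CAA"] + ["GCT"] * 21 + ["TCC"] + ["GCT"] * 35 + ["TAA"]
CDS = "".join(_CODONS)                              # 180 nt, 60 codons
INTRON = "GT" + "A" * 146 + "AG"                    # 150 nt
UTR3 = "T" * 141 + "CC" + "T" * 7                   # 150 nt; *142,*143 = C,C
TX_SEQ = UTR5 + CDS[:90] + INTRON + CDS[90:] + UTR3  # 540 nt

assert UTR5[55] == "G" and UTR5[56] == "G"   # c.-5, c.-4
assert CDS[70] == "C"                        # c.71 (Ser24 TCC middle base)
assert UTR3[141] == "C" and UTR3[142] == "C"  # c.*142, c.*143


def _build_gene(start, strand, gene_id, tx_id):
    """Place the designed transcript at `start` on either strand."""
    segments = [
        ("utr5", UTR5), ("cds", CDS[:90]), ("intron", INTRON),
        ("cds", CDS[90:]), ("utr3", UTR3),
    ]
    L = len(TX_SEQ)
    ivs = {"utr5": [], "cds": [], "intron": [], "utr3": []}
    off = 0
    for typ, seq in segments:
        n = len(seq)
        if strand == "+":
            s, e = start + off, start + off + n - 1
        else:
            s, e = start + (L - off - n), start + (L - off - 1)
        ivs[typ].append((s, e))
        off += n
    exonic = sorted(ivs["utr5"] + ivs["cds"] + ivs["utr3"])
    exons = []
    for s, e in exonic:
        if exons and s == exons[-1][1] + 1:
            exons[-1] = (exons[-1][0], e)
        else:
            exons.append((s, e))
    tx = Transcript(
        transcript_id=tx_id, gene_id=gene_id, gene_name=gene_id,
        chrom="chrT", strand=strand, exons=exons, cds=sorted(ivs["cds"]),
        utr5=sorted(ivs["utr5"]), utr3=sorted(ivs["utr3"]),
    )
    genomic = TX_SEQ if strand == "+" else revcomp(TX_SEQ)
    return genomic, tx


GENE_P_START = 101   # plus strand: spans 101..640
GENE_M_START = 801   # minus strand twin: spans 801..1340
CHRT_LEN = 1500


@pytest.fixture(scope="session")
def toy():
    """(reference, models) with the handcrafted plus/minus gene pair."""
    seq = list("ACGT" * (CHRT_LEN // 4))
    gp_seq, tx_p = _build_gene(GENE_P_START, "+", "GP", "TXP")
    gm_seq, tx_m = _build_gene(GENE_M_START, "-", "GM", "TXM")
    seq[GENE_P_START - 1: GENE_P_START - 1 + len(gp_seq)] = list(gp_seq)
    seq[GENE_M_START - 1: GENE_M_START - 1 + len(gm_seq)] = list(gm_seq)
    reference = Reference({"chrT": "".join(seq)})
    models = GeneModelSet(transcripts={"TXP": tx_p, "TXM": tx_m})
    return reference, models


def gp_pos(transcript_offset):
    """chrT position of a transcription-sense offset in the plus gene."""
    return GENE_P_START + transcript_offset


def gm_pos(transcript_offset):
    """chrT position of the same offset in the minus-strand twin."""
    return GENE_M_START + (len(TX_SEQ) - transcript_offset - 1)


# ---------------------------------------------------------------------------
# Synthetic datasets
# ---------------------------------------------------------------------------

SMALL_SIM = dict(
    seed=11, n_samples=8, n_genes=24, genome_length=260_000,
    lognorm_mu=5.8, n_near_empty=1, n_alkyl_dominant=1,
    planted_hotspots=[PlantedHotspot("UTR3", 5, 2),
                      PlantedHotspot("CODING", 4, 1)],
    planted_drivers=[PlantedDriver("UTR5", 5)],
    n_artifacts_per_reason=8, n_germline_sites=10, n_pon_sites=10,
)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A compact end-to-end dataset shared across test modules."""
    outdir = tmp_path_factory.mktemp("small_ds")
    config = SimulationConfig(**SMALL_SIM)
    data = generate_dataset(config, outdir)
    data["config"] = config
    return data


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
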