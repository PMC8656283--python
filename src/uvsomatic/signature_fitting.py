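"""Per-sample 96-context profiles and mutational-signature refitting.

Signature contributions ("SC") are estimated by nonnegative least squares
of the frequency-normalized 96-channel profile against the rows of a
predefined signature matrix, then renormalized to sum to one.  The fit is
deterministic; samples below ``min_mutations`` single-base substitutions
are excluded, mirroring the exclusion of sparsely mutated samples from
signature analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .mutation_classes import CONTEXT_LABELS

N_CHANNELS = 96

#: default minimum number of SNVs for a sample to be fit
DEFAULT_MIN_MUTATIONS = 30


@dataclass
class SampleProfile:
    sample_id: str
    counts: np.ndarray  # 96 nonnegative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CHANNELS,):
            raise ValueError("profile must have 96 channels")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros(N_CHANNELS)
        return self.counts / self.total


class SignatureMatrix:
    """Named signatures x 96 channel probabilities (rows sum to 1)."""

    def __init__(self, names, matrix):
        self.names = list(names)
        self.matrix = np.asarray(matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape != (len(self.names), N_CHANNELS):
            raise ValueError("matrix must be signatures x 96")
        if len(self.names) == 0:
            raise ValueError("signature matrix has zero rows")
        if (self.matrix < 0).any():
            raise ValueError("signature probabilities must be >= 0")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("every signature row must sum to 1")

    def __len__(self):
        return len(self.names)

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        """Read a TSV with context labels in the first column and one
        column per signature."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.loc[CONTEXT_LABELS]  # enforce canonical channel order
        return cls(df.columns.tolist(), df.to_numpy().T)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.matrix.T, index=CONTEXT_LABELS, columns=self.names)
        df.index.name = "context"
        df.to_csv(path, sep="\t", float_format="%.8g")


@dataclass
class SignatureFit:
    sample_id: str
    contributions: dict  # signature name -> fraction, sums to 1
    reconstruction_error: float  # cosine distance, observed vs reconstructed


def build_96_profile(records, sample_id=None) -> SampleProfile:
    """Count SNV context channels; DBS and indels are excluded."""
    counts = np.zeros(N_CHANNELS, dtype=np.int64)
    sid = sample_id
    for rec in records:
        if sid is None:
            sid = rec.sample_id
        if rec.mtype != "SNV":
            continue
        if rec.context_index is None:
            raise ValueError(
                f"SNV at {rec.chrom}:{rec.start} lacks a context index"
            )
        counts[rec.context_index] += 1
    return SampleProfile(sample_id=sid or "", counts=counts)


def _cosine_distance(a, b) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 1.0
    return float(1.0 - np.dot(a, b) / (na * nb))


def fit_signatures(profile: SampleProfile, signatures: SignatureMatrix,
                   min_mutations: int = DEFAULT_MIN_MUTATIONS):
    """NNLS refit of one profile; returns a SignatureFit or None (excluded)."""
    if profile.total < min_mutations:
        return None
    x = profile.frequencies()
    coef, _ = nnls(signatures.matrix.T, x)
    total = coef.sum()
    if total == 0:
        contributions = np.zeros(len(signatures))
    else:
        contributions = coef / total
    recon = coef @ signatures.matrix
    return SignatureFit(
        sample_id=profile.sample_id,
        contributions=dict(zip(signatures.names, contributions.tolist())),
        reconstruction_error=_cosine_distance(x, recon),
    )


def fit_cohort(profiles, signatures: SignatureMatrix,
               min_mutations: int = DEFAULT_MIN_MUTATIONS):
    """Fit every sample; returns (fits, excluded_sample_ids)."""
    fits, excluded = [], []
    for profile in profiles:
        fit = fit_signatures(profile, signatures, min_mutations)
        if fit is None:
            excluded.append(profile.sample_id)
        else:
            fits.append(fit)
    return fits, excluded


def cohort_context_frequencies(records) -> np.ndarray:
    """Cohort-wide SNV channel frequencies (both strands collapsed).

    Used as the resampling weights of the driver test's null model.
    """
    prof = build_96_profile(
        [r for r in records if r.mtype == "SNV"], sample_id="cohort"
    )
    return prof.frequencies()


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def profiles_frame(profiles) -> pd.DataFrame:
    df = pd.DataFrame(
        [p.counts for p in profiles],
        index=[p.sample_id for p in profiles],
        columns=CONTEXT_LABELS,
    )
    df.index.name = "sample"
    return df


def fits_frame(fits) -> pd.DataFrame:
    """Long-format (sample, signature, SC, reconstruction_error)."""
    rows = []
    for fit in fits:
        for name, sc in fit.contributions.items():
            rows.append(
                {"sample": fit.sample_id, "signature": name, "SC": sc,
                 "reconstruction_error": fit.reconstruction_error}
            )
    return pd.DataFrame(rows, columns=["sample", "signature", "SC",
                                       "reconstruction_error"])


# ---------------------------------------------------------------------------
# Built-in example signatures (synthetic, UV-like and alkylation-like)
# ---------------------------------------------------------------------------

def uv_alkylation_signatures() -> SignatureMatrix:
    """A small synthetic two-signature matrix for tests and simulations.

    ``UV`` concentrates C>T mass at dipyrimidine contexts (pyrimidine 5'
    neighbour), the hallmark of UV photoproduct mutagenesis, with a small
    C>A remainder; ``ALKYL`` concentrates C>T mass at 5'-purine contexts,
    the pattern associated with alkylating-agent exposure, with a small
    T>C remainder.  The supports barely overlap, which makes mixtures
    identifiable; these are illustrative patterns, not COSMIC data.
    """
    from .mutation_classes import context_index_of

    uv = np.zeros(N_CHANNELS)
    alk = np.zeros(N_CHANNELS)
    for five in "ACGT":
        for three in "ACGT":
            k = context_index_of(five, "C", "T", three)
            if five in "CT":  # dipyrimidine
                uv[k] = 0.30 if five == "T" else 0.175
            else:
                alk[k] = 0.30 if five == "G" else 0.175
            uv[context_index_of(five, "C", "A", three)] += 0.05 / 16
            alk[context_index_of(five, "T", "C", three)] += 0.05 / 16
    uv /= uv.sum()
    alk /= alk.sum()
    return SignatureMatrix(["UV", "ALKYL"], np.vstack([uv, alk]))
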