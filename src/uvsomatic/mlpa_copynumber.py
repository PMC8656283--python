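"""Relative copy number from MLPA probe signals.

Each probe's signal is divided by the geometric mean of the control-probe
signals in the same run (cancelling run-to-run variation), the tumor
normalized signal is divided by the matched-normal normalized signal, and
the ratio is multiplied by 2 so that the diploid neutral state reads 2.0.
Gain/loss calls use symmetric default thresholds around the integer copy
states (loss <= 1.6, gain >= 2.4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_LOSS_THRESHOLD = 1.6
DEFAULT_GAIN_THRESHOLD = 2.4


@dataclass
class Probe:
    probe_id: str
    chrom: str
    pos: int
    target: str
    is_control: bool


class MLPAProbeSet:
    def __init__(self, probes):
        self.probes = list(probes)
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise ValueError("probe ids must be unique")
        self.controls = [p.probe_id for p in self.probes if p.is_control]
        if len(self.controls) < 2:
            raise ValueError("need at least 2 control probes")
        self.noncontrols = [p.probe_id for p in self.probes if not p.is_control]
        self._by_id = {p.probe_id: p for p in self.probes}

    def __getitem__(self, probe_id):
        return self._by_id[probe_id]

    def __len__(self):
        return len(self.probes)

    @classmethod
    def from_tsv(cls, path) -> "MLPAProbeSet":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(
            Probe(str(r.probe_id), str(r.chrom), int(r.pos), str(r.target),
                  bool(r.is_control))
            for r in df.itertuples()
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [{"probe_id": p.probe_id, "chrom": p.chrom, "pos": p.pos,
              "target": p.target, "is_control": p.is_control}
             for p in self.probes]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class MLPAResult:
    sample_id: str
    copy_number: dict  # non-control probe id -> relative CN (neutral = 2.0)
    calls: dict = None  # probe id -> loss | neutral | gain


def _geomean_controls(signals, probes: MLPAProbeSet) -> float:
    vals = []
    for pid in probes.controls:
        if pid not in signals:
            raise ValueError(f"missing control probe {pid}")
        v = signals[pid]
        if v <= 0:
            raise ValueError(f"nonpositive control signal for probe {pid}")
        vals.append(v)
    return float(np.exp(np.mean(np.log(vals))))


def normalize_mlpa(tumor_signals, normal_signals,
                   probes: MLPAProbeSet, sample_id: str = "") -> MLPAResult:
    """Relative CN = 2 * (tumor/geomean(tumor controls)) / (normal/...)."""
    g_t = _geomean_controls(tumor_signals, probes)
    g_n = _geomean_controls(normal_signals, probes)
    cn = {}
    for pid in probes.noncontrols:
        for signals, label in ((tumor_signals, "tumor"),
                               (normal_signals, "normal")):
            if pid not in signals:
                raise ValueError(f"missing probe {pid} in {label} sample")
        n_t = tumor_signals[pid] / g_t
        n_n = normal_signals[pid] / g_n
        if n_n <= 0:
            raise ValueError(f"nonpositive normal signal for probe {pid}")
        cn[pid] = 2.0 * n_t / n_n
    return MLPAResult(sample_id=sample_id, copy_number=cn)


def call_cna(result: MLPAResult,
             loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
             gain_threshold: float = DEFAULT_GAIN_THRESHOLD) -> MLPAResult:
    if not loss_threshold < 2 < gain_threshold:
        raise ValueError("need loss_threshold < 2 < gain_threshold")
    calls = {}
    for pid, cn in result.copy_number.items():
        if cn <= loss_threshold:
            calls[pid] = "loss"
        elif cn >= gain_threshold:
            calls[pid] = "gain"
        else:
            calls[pid] = "neutral"
    result.calls = calls
    return result


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def load_signal_table(path) -> dict:
    """sample -> {probe_id: intensity} from a (sample, probe, intensity) TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "probe": str})
    out = {}
    for r in df.itertuples():
        out.setdefault(r.sample, {})[r.probe] = float(r.intensity)
    return out


def write_signal_table(signals: dict, path) -> None:
    rows = [
        {"sample": sample, "probe": probe, "intensity": val}
        for sample in sorted(signals)
        for probe, val in sorted(signals[sample].items())
    ]
    pd.DataFrame(rows, columns=["sample", "probe", "intensity"]).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def results_frame(results, probes: MLPAProbeSet) -> pd.DataFrame:
    """Bar-plot-ready long table of relative CN values and calls."""
    rows = []
    for res in results:
        for pid in probes.noncontrols:
            rows.append(
                {"sample": res.sample_id, "probe": pid,
                 "chrom": probes[pid].chrom, "pos": probes[pid].pos,
                 "target": probes[pid].target,
                 "copy_number": res.copy_number[pid],
                 "call": res.calls[pid] if res.calls else "."}
            )
    return pd.DataFrame(rows, columns=["sample", "probe", "chrom", "pos",
                                       "target", "copy_number", "call"])
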