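"""Somatic-call retention criteria plus germline / panel-of-normals flagging.

A call is retained iff it has (i) at least ``min_tumor_alt`` alternate-
supporting tumor reads, (ii) tumor allele fraction of at least
``min_tumor_af``, and (iii) tumor allele fraction at least ``min_tn_ratio``
times the normal allele fraction.  A normal allele fraction of zero
(including an uncovered normal) satisfies the ratio criterion: absence of
normal support is the strongest somatic evidence.  All thresholds are
inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

REASON_ORDER = ("low_support", "low_af", "low_ratio")


@dataclass
class FilterParams:
    min_tumor_alt: int = 5
    min_tumor_af: float = 0.05
    min_tn_ratio: float = 5.0

    def __post_init__(self):
        if self.min_tumor_alt < 0:
            raise ValueError("min_tumor_alt must be >= 0")
        if not 0 <= self.min_tumor_af <= 1:
            raise ValueError("min_tumor_af must be in [0, 1]")
        if self.min_tn_ratio < 1:
            raise ValueError("min_tn_ratio must be >= 1")


def failing_reason(call, params: FilterParams):
    """First failing criterion in fixed order, or None if the call passes."""
    if call.tumor_depth == 0:
        raise ValueError(f"uncovered site {call.chrom}:{call.pos}")
    t_af = call.tumor_af
    n_af = call.normal_af
    if call.tumor_alt < params.min_tumor_alt:
        return "low_support"
    if t_af < params.min_tumor_af:
        return "low_af"
    if n_af > 0 and t_af / n_af < params.min_tn_ratio:
        return "low_ratio"
    return None


def apply_somatic_filters(calls, params: FilterParams = None):
    """Partition calls into (passed, rejected-with-reason) lists.

    Calls already carrying a ``germline`` or ``pon`` flag are not
    considered (drop them with :func:`flag_sites` + :func:`drop_flagged`
    first, or they are evaluated like any other call here).
    """
    params = params or FilterParams()
    passed, rejected = [], []
    for call in calls:
        reason = failing_reason(call, params)
        if reason is None:
            passed.append(call)
        else:
            call.flags.add(reason)
            rejected.append((call, reason))
    return passed, rejected


def flag_sites(calls, sites, flag_name: str):
    """Add ``flag_name`` to calls whose (chrom, pos, ref, alt) key is listed.

    Returns the same call objects; the number flagged is logged.  Flagged
    calls are meant to be excluded from all downstream counting (see
    :func:`drop_flagged`).
    """
    n = 0
    for call in calls:
        if call.key in sites:
            call.flags.add(flag_name)
            n += 1
    logger.info("flagged %d calls as %s", n, flag_name)
    return calls


def drop_flagged(calls, flag_names=("germline", "pon")):
    """Remove calls carrying any of the given flags."""
    names = set(flag_names)
    return [c for c in calls if not (c.flags & names)]
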