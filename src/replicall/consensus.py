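"""Majority / strict consensus reconstruction from replicate calls.

Majority consensus assigns the category held by more than half of the
replicates; when no majority exists (e.g. three replicates all disagreeing)
the site is classified as the tie category, homozygous variant by default.
Strict consensus requires unanimity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .types import GenotypeCategory, ReconstructedCallset, SiteTable


class ConsensusMode(enum.Enum):
    MAJORITY = "majority"
    STRICT = "strict"


@dataclass(frozen=True)
class ConsensusRule:
    mode: ConsensusMode = ConsensusMode.MAJORITY
    tie_category: GenotypeCategory = GenotypeCategory.HOMALT


def consensus_call(calls, rule: ConsensusRule = ConsensusRule()) -> GenotypeCategory:
    """Consensus category for one site's replicate calls."""
    calls = np.asarray(calls, dtype=int)
    if calls.size < 2:
        raise ValueError("need >=2 replicate calls")
    counts = np.bincount(calls, minlength=3)
    if rule.mode is ConsensusMode.STRICT:
        top = int(np.argmax(counts))
        return (GenotypeCategory(top) if counts[top] == calls.size
                else rule.tie_category)
    top = int(np.argmax(counts))
    if counts[top] * 2 > calls.size:
        return GenotypeCategory(top)
    return rule.tie_category


def consensus_callset(table: SiteTable,
                      rule: ConsensusRule = ConsensusRule()) -> ReconstructedCallset:
    """Vectorized consensus over a SiteTable."""
    calls = table.calls
    n, R = calls.shape
    counts = np.stack([(calls == k).sum(axis=1) for k in range(3)], axis=1)
    top = counts.argmax(axis=1)
    topcount = counts.max(axis=1)
    if rule.mode is ConsensusMode.STRICT:
        ok = topcount == R
    else:
        ok = topcount * 2 > R
    cats = np.where(ok, top, int(rule.tie_category)).astype(np.int8)
    return ReconstructedCallset.from_sites(table, cats,
                                           model=f"consensus-{rule.mode.value}",
                                           params=rule)
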