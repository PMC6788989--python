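"""Post-genotyping variant filters: genotype quality, maximum depth, SNV
density.

Filters annotate calls with FILTER labels rather than dropping them; each
filter writes only its own label, so filters are independent, idempotent
and order-insensitive.  The depth cutoff is d + 5*sqrt(d) with d the
median read depth of the dataset; the density filter flags every call
lying in any 500-bp window that contains more than 10 calls (sliding
windows, any placement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence


@dataclass
class FilterConfig:
    gq_mode: str = "fixed"          # "fixed" or "depth_scaled"
    fixed_gq: float = 50.0
    gq_depth_coef: float = 1.0      # cutoff = coef * median depth
    density_count: int = 10
    density_window: int = 500

    def __post_init__(self) -> None:
        if self.gq_mode not in ("fixed", "depth_scaled"):
            raise ValueError("gq_mode must be 'fixed' or 'depth_scaled'")
        if min(self.fixed_gq, self.gq_depth_coef,
               self.density_count, self.density_window) <= 0:
            raise ValueError("filter thresholds must be positive")


def gq_filter(calls: Sequence, config: FilterConfig,
              median_depth: Optional[float] = None) -> List:
    """Flag calls with GQ below the cutoff as ``low_gq``.

    Fixed mode: cutoff = ``fixed_gq`` (GQ exactly at the cutoff passes).
    Depth-scaled mode: cutoff = ``gq_depth_coef`` * median depth.
    """
    if config.gq_mode == "fixed":
        cutoff = config.fixed_gq
    else:
        if median_depth is None:
            raise ValueError("depth_scaled GQ filtering needs the median depth")
        cutoff = config.gq_depth_coef * median_depth
    for call in calls:
        if call.gq < cutoff:
            call.filters.add("low_gq")
    return list(calls)


def depth_filter(calls: Sequence, median_depth: float) -> List:
    """Flag calls with depth strictly above d + 5*sqrt(d)."""
    if median_depth <= 0:
        raise ValueError("median depth must be positive")
    cutoff = median_depth + 5.0 * math.sqrt(median_depth)
    for call in calls:
        if call.depth is not None and call.depth > cutoff:
            call.filters.add("depth")
    return list(calls)


def density_filter(calls: Sequence, max_snvs: int = 10,
                   window: int = 500) -> List:
    """Flag every call inside any length-``window`` interval holding more
    than ``max_snvs`` calls.

    Equivalent to: calls i..i+max_snvs are all flagged whenever
    pos[i+max_snvs] - pos[i] < window (the max_snvs+1 of them then fit in
    one window).  Input must be coordinate-sorted.
    """
    calls = list(calls)
    by_chrom: dict = {}
    last = None
    for k, call in enumerate(calls):
        key = (call.chrom, call.pos)
        if last is not None and key < last:
            raise ValueError("density_filter requires coordinate-sorted calls")
        last = key
        by_chrom.setdefault(call.chrom, []).append(k)
    for idxs in by_chrom.values():
        pos = [calls[k].pos for k in idxs]
        for i in range(len(pos) - max_snvs):
            if pos[i + max_snvs] - pos[i] < window:
                for k in idxs[i : i + max_snvs + 1]:
                    calls[k].filters.add("density")
    return calls


def apply_filters(calls: Sequence, config: FilterConfig,
                  median_depth: float) -> List:
    """GQ, depth and density filters in sequence (order has no effect)."""
    calls = gq_filter(calls, config, median_depth)
    calls = depth_filter(calls, median_depth)
    calls = density_filter(calls, config.density_count, config.density_window)
    return calls
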