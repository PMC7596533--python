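"""Closed-loop evaluation of interval detection against planted truth.

Given detected intervals and the simulator's truth set, computes

* sensitivity — fraction of planted causal regions overlapped by at least
  one detected interval;
* precision — fraction of detected intervals overlapping at least one
  planted region;
* boundary slack — for each matched interval, the number of emitted
  variant sites its span includes beyond each edge of the planted region
  (0 = flush with the outermost causal marker, 1 = one inter-variant
  spacing outside, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .intervals import Interval
from .synthetic import Region, TruthSet


@dataclass(frozen=True)
class RecoveryReport:
    sensitivity: float
    precision: float
    n_regions: int
    n_intervals: int
    max_boundary_overhang: int  # sites beyond a region edge, worst case

    @property
    def boundaries_within_one_spacing(self) -> bool:
        return self.max_boundary_overhang <= 1


def evaluate_recovery(
    intervals: Sequence[Interval],
    truth: TruthSet,
) -> RecoveryReport:
    regions = truth.causal_regions
    region_hit = [False] * len(regions)
    n_matched = 0
    max_overhang = 0
    sites_by_chrom: dict[str, list[int]] = {}
    for row in truth.sites.itertuples():
        sites_by_chrom.setdefault(row.chrom, []).append(int(row.pos))

    for iv in intervals:
        matched = False
        for i, region in enumerate(regions):
            if region.overlaps(iv.chrom, iv.start, iv.end):
                region_hit[i] = True
                matched = True
                max_overhang = max(
                    max_overhang, _overhang(iv, region, sites_by_chrom[iv.chrom])
                )
        n_matched += matched

    sensitivity = (sum(region_hit) / len(regions)) if regions else float("nan")
    precision = (n_matched / len(intervals)) if intervals else float("nan")
    return RecoveryReport(
        sensitivity=sensitivity,
        precision=precision,
        n_regions=len(regions),
        n_intervals=len(intervals),
        max_boundary_overhang=max_overhang,
    )


def _overhang(iv: Interval, region: Region, sites: list[int]) -> int:
    """Emitted sites inside the interval span but outside the region edge."""
    left = sum(1 for p in sites if iv.start <= p < region.start)
    right = sum(1 for p in sites if region.end < p <= iv.end)
    return max(left, right)
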