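"""Seeded run-detection of candidate intervals from pooled allele frequencies.

The detection criterion is a series of near-zero AFe values in the pool
whose phenotype matches the reference sequence. A site *qualifies* when the
matching pool's AFe is at or below ``run_max_afe`` (default 0.1). A *seed*
is a qualifying site whose pools additionally diverge beyond the
error-adjusted threshold::

    X = P - 100 * E / C

with bulked-pool phenotypic difference ``P`` (default 0.9), per-base
sequencing-error rate ``E`` (default 0.01), and combined informative
coverage ``C`` of the two pools at the site — X relaxes the divergence
requirement just enough to permit the handful of error reads expected at
that coverage.

From each seed an interval extends left and right through consecutive
qualifying sites. A short interruption — at most ``max_interruption``
consecutive non-qualifying sites (default 1) flanked on both sides by
qualifying sites — is absorbed; anything longer terminates extension at the
last qualifying site. Overlapping extensions merge; intervals with fewer
than ``min_variants`` qualifying members are discarded. An interval spans
its first to last member marker (no midpoint extension), so detected
regions are resolvable intervals between two marker loci. No confidence
level is attached to an interval; detection is descriptive.

:func:`enumerate_intervals_bruteforce` is an independent reference route —
exhaustive enumeration of maximal tolerant runs — kept for validation of
the seed-extension implementation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pool_afe import AFeRecord
from .stitch import SPACER, LiftoverTable


@dataclass(frozen=True)
class IntervalParams:
    """Detection thresholds.

    ``matching_pool`` names which AFe column ("a" or "b") belongs to the
    pool phenotypically matching the reference sequence. Setting the error
    rate ``E`` to 0 reduces seeding to a flat ``delta >= P`` rule.
    """

    p_diff: float = 0.9          # bulked-pool phenotypic difference P
    error_rate: float = 0.01     # sequencing error rate E
    run_max_afe: float = 0.1     # qualifying threshold on matching-pool AFe
    delta_report_threshold: float = 0.9
    max_interruption: int = 1
    min_variants: int = 2
    matching_pool: str = "a"

    def __post_init__(self) -> None:
        if not 0 < self.run_max_afe < self.p_diff <= 1:
            raise ValueError("require 0 < run_max_afe < P <= 1")
        if self.error_rate < 0:
            raise ValueError("error rate E must be >= 0")
        if self.matching_pool not in ("a", "b"):
            raise ValueError("matching_pool must be 'a' or 'b'")
        if self.max_interruption < 0 or self.min_variants < 1:
            raise ValueError("max_interruption >= 0 and min_variants >= 1 required")


@dataclass(frozen=True)
class Interval:
    """A detected genomic interval spanning its member marker loci."""

    chrom: str
    start: int  # 1-based inclusive, position of first member variant
    end: int    # 1-based inclusive, position of last member variant
    seed_pos: int
    member_sites: tuple[int, ...]  # qualifying sites, ascending

    def __post_init__(self) -> None:
        if not self.start <= self.seed_pos <= self.end:
            raise ValueError("seed must lie within the interval")

    @property
    def n_variants(self) -> int:
        return len(self.member_sites)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def seed_threshold(coverage: float, p_diff: float = 0.9,
                   error_rate: float = 0.01) -> float:
    """Error-adjusted divergence threshold ``X = P - 100 * E / C``."""
    if coverage <= 0:
        raise ValueError("combined coverage C must be positive")
    return p_diff - 100.0 * error_rate / coverage


def matching_afe(record: AFeRecord, params: IntervalParams) -> float:
    return record.afe_a if params.matching_pool == "a" else record.afe_b


def is_qualifying(record: AFeRecord, params: IntervalParams) -> bool:
    return matching_afe(record, params) <= params.run_max_afe


def is_seed(record: AFeRecord, params: IntervalParams) -> bool:
    """Seed = qualifying site whose delta meets the per-site threshold X."""
    if not is_qualifying(record, params):
        return False
    x = seed_threshold(record.coverage, params.p_diff, params.error_rate)
    return record.delta >= x


def find_seeds(records: Sequence[AFeRecord],
               params: IntervalParams = IntervalParams()) -> list[tuple[str, int]]:
    """(chrom, pos) of every seed site in a coordinate-sorted record stream."""
    return [(r.chrom, r.pos) for r in records if is_seed(r, params)]


def _group_records(
    records: Sequence[AFeRecord],
    liftover: LiftoverTable | None,
) -> list[tuple[str, list[AFeRecord]]]:
    """Split records per chromosome — and per source scaffold when stitched.

    With a liftover table, sites on a super-scaffold are partitioned by
    their source scaffold so intervals never span an N-spacer gap.
    """
    groups: dict[tuple[str, str], list[AFeRecord]] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        sub = ""
        if liftover is not None:
            try:
                hit = liftover.lift_to_source(rec.chrom, rec.pos)
            except KeyError:
                hit = None
            if hit == SPACER:
                continue  # a variant cannot sit on a spacer base
            if hit is not None:
                sub = hit[0]
        key = (rec.chrom, sub)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)
    out = []
    for key in order:
        recs = sorted(groups[key], key=lambda r: r.pos)
        out.append((key[0], recs))
    return out


def _extend_from_seed(
    qual: np.ndarray, seed_idx: int, max_interruption: int
) -> tuple[int, int]:
    """Indices [i, j] of the maximal tolerant run around a qualifying seed."""
    n = len(qual)
    j = seed_idx
    while True:
        k = j + 1
        # absorb a flanked interruption of <= max_interruption sites
        gap = 0
        while k < n and not qual[k] and gap < max_interruption:
            k += 1
            gap += 1
        if k < n and qual[k]:
            j = k
        else:
            break
    i = seed_idx
    while True:
        k = i - 1
        gap = 0
        while k >= 0 and not qual[k] and gap < max_interruption:
            k -= 1
            gap += 1
        if k >= 0 and qual[k]:
            i = k
        else:
            break
    return i, j


def detect_intervals(
    records: Sequence[AFeRecord],
    params: IntervalParams = IntervalParams(),
    liftover: LiftoverTable | None = None,
) -> list[Interval]:
    """Detect candidate intervals by seeded run extension.

    ``records`` must be coordinate-sorted and coverage-band filtered.
    Chromosomes (and, when a stitch liftover table is supplied, source
    scaffolds within super-scaffolds) are processed independently. Output is
    sorted and non-overlapping; results do not depend on seed processing
    order.
    """
    intervals: list[Interval] = []
    for chrom, recs in _group_records(records, liftover):
        qual = np.array([is_qualifying(r, params) for r in recs], dtype=bool)
        seed_idx = [i for i, r in enumerate(recs) if is_seed(r, params)]
        spans: dict[tuple[int, int], int] = {}  # (i, j) -> first seed index
        for s in seed_idx:
            span = _extend_from_seed(qual, s, params.max_interruption)
            spans.setdefault(span, s)
        merged = _merge_spans(spans)
        for (i, j), s in merged:
            members = tuple(recs[t].pos for t in range(i, j + 1) if qual[t])
            if len(members) < params.min_variants:
                continue
            intervals.append(Interval(
                chrom=chrom,
                start=recs[i].pos,
                end=recs[j].pos,
                seed_pos=recs[s].pos,
                member_sites=members,
            ))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start))
    return intervals


def _merge_spans(
    spans: dict[tuple[int, int], int]
) -> list[tuple[tuple[int, int], int]]:
    """Merge overlapping index spans; keep the leftmost seed of each merge."""
    merged: list[tuple[tuple[int, int], int]] = []
    for (i, j), s in sorted(spans.items()):
        if merged and i <= merged[-1][0][1]:
            (pi, pj), ps = merged[-1]
            merged[-1] = ((pi, max(pj, j)), min(ps, s))
        else:
            merged.append(((i, j), s))
    return merged


def enumerate_intervals_bruteforce(
    records: Sequence[AFeRecord],
    params: IntervalParams = IntervalParams(),
) -> list[Interval]:
    """Reference detector: exhaustive enumeration of maximal tolerant runs.

    Considers every pair of qualifying sites (i, j) on a chromosome, checks
    that no run of more than ``max_interruption`` consecutive non-qualifying
    sites lies strictly inside, requires at least one seed and
    ``min_variants`` qualifying members, then discards runs contained in a
    larger valid run. Quadratic in the number of sites; used to validate
    :func:`detect_intervals` on small instances.
    """
    intervals: list[Interval] = []
    for chrom, recs in _group_records(records, None):
        n = len(recs)
        qual = [is_qualifying(r, params) for r in recs]
        seed = [is_seed(r, params) for r in recs]
        # bad[t]: sites t-max_interruption..t are all non-qualifying, i.e. a
        # too-long interruption block ends at t
        m = params.max_interruption
        bad = [False] * n
        for t in range(n):
            if t - m >= 0 and all(not qual[u] for u in range(t - m, t + 1)):
                bad[t] = True
        # next_bad[t]: smallest bad position >= t (n if none); prefix counts
        # of seeds and qualifying sites make per-pair checks O(1)
        next_bad = [n] * (n + 1)
        for t in range(n - 1, -1, -1):
            next_bad[t] = t if bad[t] else next_bad[t + 1]
        seed_cum = [0] * (n + 1)
        qual_cum = [0] * (n + 1)
        for t in range(n):
            seed_cum[t + 1] = seed_cum[t] + int(seed[t])
            qual_cum[t + 1] = qual_cum[t] + int(qual[t])
        # exhaustive enumeration: for every qualifying start i keep the
        # largest valid end j (smaller ends are contained runs)
        best_end: dict[int, int] = {}
        for i in range(n):
            if not qual[i]:
                continue
            for j in range(i, n):
                if not qual[j]:
                    continue
                # a violating block must lie strictly inside (i, j):
                # some bad t with i + m + 1 <= t <= j - 1
                t = next_bad[min(i + m + 1, n)]
                if t <= j - 1:
                    continue
                if seed_cum[j + 1] - seed_cum[i] == 0:
                    continue
                if qual_cum[j + 1] - qual_cum[i] < params.min_variants:
                    continue
                best_end[i] = j
        maximal = [
            (i, j) for i, j in sorted(best_end.items())
            if not any(
                i2 <= i and j <= best_end[i2] and (i2, best_end[i2]) != (i, j)
                for i2 in best_end
            )
        ]
        for i, j in sorted(maximal):
            members = tuple(recs[t].pos for t in range(i, j + 1) if qual[t])
            first_seed = next(t for t in range(i, j + 1) if seed[t])
            intervals.append(Interval(
                chrom=chrom, start=recs[i].pos, end=recs[j].pos,
                seed_pos=recs[first_seed].pos, member_sites=members,
            ))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start))
    return intervals


def report_interval_variants(
    interval: Interval,
    records: Sequence[AFeRecord],
    params: IntervalParams = IntervalParams(),
) -> list[AFeRecord]:
    """Sites within the interval span whose delta meets the report threshold.

    Absorbed interruption sites sit inside the span but fall out of the
    report unless their own delta clears the threshold.
    """
    return [
        r for r in records
        if r.chrom == interval.chrom
        and interval.start <= r.pos <= interval.end
        and r.delta >= params.delta_report_threshold
    ]


def interval_summary(intervals: Sequence[Interval]) -> dict:
    """Count and min/max/mean length of detected intervals (kb-scale stats)."""
    if not intervals:
        return {"count": 0, "min_length": None, "max_length": None,
                "mean_length": None}
    lengths = [iv.length for iv in intervals]
    return {
        "count": len(intervals),
        "min_length": int(min(lengths)),
        "max_length": int(max(lengths)),
        "mean_length": float(np.mean(lengths)),
    }


# ---------------------------------------------------------------------------
# exports


def intervals_to_dataframe(intervals: Sequence[Interval]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "seed_pos": iv.seed_pos, "n_variants": iv.n_variants,
            "length": iv.length,
        }
        for iv in intervals
    ], columns=["chrom", "start", "end", "seed_pos", "n_variants", "length"])


def write_intervals_bed(intervals: Sequence[Interval], path: str | Path) -> None:
    """BED export, 0-based half-open."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals, start=1):
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\tinterval_{i}\n")


def write_plot_table(records: Sequence[AFeRecord], path: str | Path) -> None:
    """Per-site delta-AFe track (chrom, pos, afe_a, afe_b, delta) for plotting."""
    pd.DataFrame([
        {"chrom": r.chrom, "pos": r.pos, "afe_a": r.afe_a,
         "afe_b": r.afe_b, "delta": r.delta}
        for r in records
    ], columns=["chrom", "pos", "afe_a", "afe_b", "delta"]).to_csv(
        path, sep="\t", index=False)


def plot_delta_tracks(
    records: Sequence[AFeRecord],
    intervals: Sequence[Interval],
    path: str | Path,
    delta_line: float = 0.9,
) -> None:
    """Render per-chromosome delta-AFe tracks with interval shading.

    A horizontal reference line marks the homozygote-dissimilarity
    threshold; detected intervals are shaded.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({r.chrom for r in records})
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 2.2 * max(len(chroms), 1)), squeeze=False
    )
    by_chrom: dict[str, list[AFeRecord]] = {c: [] for c in chroms}
    for r in records:
        by_chrom[r.chrom].append(r)
    for ax, chrom in zip(axes[:, 0], chroms):
        recs = by_chrom[chrom]
        ax.scatter([r.pos for r in recs], [r.delta for r in recs],
                   s=4, c="0.4", linewidths=0)
        ax.axhline(delta_line, color="red", linestyle=":", linewidth=1)
        for iv in intervals:
            if iv.chrom == chrom:
                ax.axvspan(iv.start, iv.end, color="pink", alpha=0.5)
        ax.set_ylim(-0.05, 1.05)
        ax.set_ylabel("delta-AFe")
        ax.set_title(chrom, fontsize=9)
    axes[-1, 0].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_summary_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
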