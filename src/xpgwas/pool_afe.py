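"""Pooled allele-frequency estimation from a joint two-pool VCF.

The input is a joint-called VCF whose two samples are DNA pools of
phenotypically contrasting individuals. For each biallelic site the allele
frequency estimate (AFe) per pool is the fraction of informative reads
supporting the alternative allele::

    AFe = alt_reads / (ref_reads + alt_reads)

so AFe = 0 means every read supports the reference allele and AFe = 1 means
every read supports the alternative. delta-AFe is the absolute difference
of the two pools' AFe; values near 1 flag homozygote dissimilarity between
pools.

Before estimation, sites pass rule-based hard filters (biallelic, both
pools genotyped, per-pool DP and GQ thresholds, optional site-annotation
thresholds), and afterwards a coverage band retains only sites whose
informative depth lies within a multiplicative band around the mean depth —
discarding low-confidence sparse sites and collapsed-repeat pileups.
"""

from __future__ import annotations

import json
import logging
import operator
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

# fixed precedence of removal reasons in the filter tally
FILTER_REASONS = ("multiallelic", "missing_genotype", "DP", "GQ", "site_filter")

_OPS = {"<": operator.lt, ">": operator.gt, "<=": operator.le, ">=": operator.ge}


@dataclass(frozen=True)
class PoolSample:
    """Per-pool sample data at one site."""

    ref_count: int
    alt_count: int
    depth: int | None
    gq: int | None
    genotyped: bool

    @property
    def informative(self) -> int:
        """Reads supporting either the reference or the alternative allele."""
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class PooledVariant:
    """One variant site with per-pool read support."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    samples: Mapping[str, PoolSample]
    info: Mapping[str, float] = field(default_factory=dict)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    @property
    def variant_class(self) -> str:
        """"SNP" if all allele lengths match the reference, else "InDel"."""
        if any(len(alt) != len(self.ref_allele) for alt in self.alt_alleles):
            return "InDel"
        return "SNP"


@dataclass(frozen=True)
class AFeRecord:
    """Per-site allele-frequency estimates for the two pools."""

    chrom: str
    pos: int
    afe_a: float
    afe_b: float
    used_a: int  # informative reads, pool A
    used_b: int  # informative reads, pool B

    @property
    def delta(self) -> float:
        return abs(self.afe_a - self.afe_b)

    @property
    def coverage(self) -> int:
        """Combined informative coverage of the two pools (C)."""
        return self.used_a + self.used_b


@dataclass(frozen=True)
class FilterParams:
    """Hard-filter and coverage-band thresholds.

    DP and GQ thresholds apply per pool: both pools must pass. The coverage
    band is expressed as multipliers of the mean depth; boundary values are
    inclusive. ``site_filters`` optionally maps an INFO annotation to an
    (operator, threshold) pair that *fails* a record when satisfied, e.g.
    ``{"QD": ("<", 2.0), "FS": (">", 60.0)}``; records lacking the
    annotation are not failed by it.
    """

    min_dp: int = 15
    min_gq: int = 20
    biallelic_only: bool = True
    require_both_genotyped: bool = True
    coverage_band: tuple[float, float] = (0.75, 2.5)
    coverage_band_mode: str = "per-pool"  # or "combined"
    site_filters: Mapping[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        low, high = self.coverage_band
        if not 0 < low < high:
            raise ValueError("coverage band requires 0 < low multiplier < high")
        if self.coverage_band_mode not in ("per-pool", "combined"):
            raise ValueError("coverage_band_mode must be 'per-pool' or 'combined'")


def read_pooled_vcf(
    path: str | Path,
    pool_names: tuple[str, str],
) -> list[PooledVariant]:
    """Read a joint VCF into coordinate-sorted :class:`PooledVariant` records.

    The file must contain exactly the two named samples with per-sample AD
    (allele depth), DP, GQ and GT FORMAT fields. Multi-allelic records are
    passed through for the hard filter to remove and tally.
    """
    variants: list[PooledVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        present = list(vcf.header.samples)
        for name in pool_names:
            if name not in present:
                raise ValueError(
                    f"sample {name!r} not in VCF (samples: {present})"
                )
        for rec in vcf:
            samples: dict[str, PoolSample] = {}
            for name in pool_names:
                call = rec.samples[name]
                ad = call.get("AD")
                if ad is None or all(v is None for v in ad):
                    raise ValueError(
                        f"record {rec.chrom}:{rec.pos} sample {name}: missing AD field"
                    )
                ref_count = int(ad[0] or 0)
                # for multiallelic records, pool all non-reference support
                alt_count = int(sum(v or 0 for v in ad[1:]))
                gt = call.get("GT")
                genotyped = gt is not None and all(a is not None for a in gt)
                dp = call.get("DP")
                gq = call.get("GQ")
                samples[name] = PoolSample(
                    ref_count=ref_count,
                    alt_count=alt_count,
                    depth=int(dp) if dp is not None else None,
                    gq=int(gq) if gq is not None else None,
                    genotyped=genotyped,
                )
            info = {
                k: float(v)
                for k, v in rec.info.items()
                if isinstance(v, (int, float))
            }
            variants.append(PooledVariant(
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_alleles=tuple(rec.alts or ()),
                samples=samples,
                info=info,
            ))
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants


def hard_filter(
    variants: Iterable[PooledVariant],
    params: FilterParams = FilterParams(),
) -> tuple[list[PooledVariant], Counter]:
    """Apply post-call hard filters; return survivors and a per-reason tally.

    A removed record is counted once, under the first matching reason in the
    fixed order multiallelic → missing genotype → DP → GQ → site filters.
    The tally also carries a ``"pass"`` count, so raw = pass + removals.
    """
    survivors: list[PooledVariant] = []
    tally: Counter = Counter({reason: 0 for reason in FILTER_REASONS})
    tally["pass"] = 0
    for v in variants:
        reason = _first_failure(v, params)
        if reason is None:
            survivors.append(v)
            tally["pass"] += 1
        else:
            tally[reason] += 1
            logger.debug("removed %s:%d (%s)", v.chrom, v.pos, reason)
    return survivors, tally


def _first_failure(v: PooledVariant, params: FilterParams) -> str | None:
    if params.biallelic_only and not v.is_biallelic:
        return "multiallelic"
    pools = list(v.samples.values())
    if params.require_both_genotyped and not all(s.genotyped for s in pools):
        return "missing_genotype"
    if any(s.depth is None or s.depth < params.min_dp for s in pools):
        return "DP"
    if any(s.gq is None or s.gq < params.min_gq for s in pools):
        return "GQ"
    for ann, (op, threshold) in params.site_filters.items():
        if ann in v.info and _OPS[op](v.info[ann], threshold):
            return "site_filter"
    return None


def compute_afe(
    variant: PooledVariant,
    pool_names: tuple[str, str],
) -> AFeRecord | None:
    """Per-pool AFe and delta-AFe for one biallelic site.

    Uses informative reads (ref + alt support), not the DP field, which may
    include reads assigned to neither allele. Returns ``None`` (logged) when
    either pool has zero informative reads.
    """
    if not variant.is_biallelic:
        raise ValueError(
            f"{variant.chrom}:{variant.pos}: AFe requires a biallelic site"
        )
    a = variant.samples[pool_names[0]]
    b = variant.samples[pool_names[1]]
    if a.informative == 0 or b.informative == 0:
        logger.debug("skipping %s:%d: zero informative reads in a pool",
                     variant.chrom, variant.pos)
        return None
    return AFeRecord(
        chrom=variant.chrom,
        pos=variant.pos,
        afe_a=a.alt_count / a.informative,
        afe_b=b.alt_count / b.informative,
        used_a=a.informative,
        used_b=b.informative,
    )


def compute_afe_table(
    variants: Iterable[PooledVariant],
    pool_names: tuple[str, str],
) -> list[AFeRecord]:
    """AFe records for every site with informative reads in both pools."""
    out = []
    for v in variants:
        rec = compute_afe(v, pool_names)
        if rec is not None:
            out.append(rec)
    return out


def mean_informative_depth(records: Sequence[AFeRecord]) -> tuple[float, float]:
    """Arithmetic mean informative depth per pool over the record set."""
    if not records:
        raise ValueError("cannot estimate mean depth from an empty record set")
    return (
        float(np.mean([r.used_a for r in records])),
        float(np.mean([r.used_b for r in records])),
    )


def coverage_band_filter(
    records: Sequence[AFeRecord],
    mean_depths: tuple[float, float] | None = None,
    params: FilterParams = FilterParams(),
) -> list[AFeRecord]:
    """Retain sites whose informative depth lies within the coverage band.

    In ``per-pool`` mode (default) each pool's informative reads must lie
    within ``[low * mean, high * mean]`` of that pool's own mean depth,
    bounds inclusive. In ``combined`` mode the summed coverage C is compared
    against the combined mean. ``mean_depths`` defaults to the means over
    ``records`` themselves.
    """
    if not records:
        return []
    low, high = params.coverage_band
    if mean_depths is None:
        mean_depths = mean_informative_depth(records)
    mean_a, mean_b = mean_depths
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("mean depths must be positive")
    if params.coverage_band_mode == "combined":
        mean_c = mean_a + mean_b
        return [r for r in records if low * mean_c <= r.coverage <= high * mean_c]
    return [
        r for r in records
        if low * mean_a <= r.used_a <= high * mean_a
        and low * mean_b <= r.used_b <= high * mean_b
    ]


# ---------------------------------------------------------------------------
# table I/O


def afe_to_dataframe(records: Sequence[AFeRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "chrom": r.chrom, "pos": r.pos,
            "afe_a": r.afe_a, "afe_b": r.afe_b, "delta": r.delta,
            "used_a": r.used_a, "used_b": r.used_b, "coverage": r.coverage,
        }
        for r in records
    ], columns=["chrom", "pos", "afe_a", "afe_b", "delta",
                "used_a", "used_b", "coverage"])


def write_afe_tsv(records: Sequence[AFeRecord], path: str | Path) -> None:
    afe_to_dataframe(records).to_csv(path, sep="\t", index=False)


def read_afe_tsv(path: str | Path) -> list[AFeRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        AFeRecord(
            chrom=str(row.chrom), pos=int(row.pos),
            afe_a=float(row.afe_a), afe_b=float(row.afe_b),
            used_a=int(row.used_a), used_b=int(row.used_b),
        )
        for row in df.itertuples()
    ]


def write_filter_tally(tally: Counter, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(tally), indent=2) + "\n")
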