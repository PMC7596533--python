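"""Synthetic pooled-sequencing and chemotype-panel generation with truth.

The generator emulates the data a two-pool extreme-phenotype resequencing
experiment produces, with known ground truth, so every downstream stage
(hard filtering, AFe estimation, coverage banding, interval detection, pool
selection) can be tested closed-loop without external data.

Pool-seq model
--------------
Candidate variant positions fall uniformly at ``variant_rate`` per base.
Background sites share one true alternative-allele frequency ``p`` between
the pools (drawn from a configurable mixture of fixed-reference and
Uniform(0, 1) segregating sites — pools sampled from one population agree
in expectation). Sites inside a planted causal region are fixed-different:
``p = 0`` in the reference-matching pool and ``p = 1`` in the other. Per
pool, sequencing draws depth ``d`` (Poisson around the pool mean, or
constant), then alternative reads ``~ Binomial(d, p(1-E) + (1-p)E)`` with
error rate ``E``; reference reads are the remainder.

By default a site is written to the VCF only when at least one pool's
called genotype is non-reference, mirroring a joint variant caller's
output: a site at which both pools are confidently homozygous reference is
not a variant and would never appear in real joint-called input. Set
``emit_monomorphic=True`` to keep every candidate site.

Collapsed-paralog loci (multiple gene copies mapping to one locus, seen as
~3x read pileups) can be planted via per-region depth multipliers to
exercise the coverage-band filter.

Chemotype model
---------------
Panel dicyclic fractions follow a three-component (low / intermediate /
high) mixture and C3-alkyl fractions a low-skewed distribution with a small
high-C3 minority. Planted extreme individuals draw their fractions from
narrow joint-extreme ranges matching real extreme-pool chemotypes. Analyte
concentrations are back-calculated so the fraction computation inverts the
draw exactly: the eight analytes factorise as
(di/tri-cyclic) x (C3/C5-alkyl) x (acid/neutral).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemotype import ANALYTES
from .pool_afe import PooledVariant, PoolSample

VCF_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
##source=xpgwas-synthetic
##FILTER=<ID=PASS,Description="All filters passed">
{contigs}##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples with data">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_a}\t{sample_b}
"""

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start <= self.end and self.start <= end


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the pooled-sequencing simulation.

    Defaults reflect the experimental regime the package targets: two pools
    at ~55x mean depth, Illumina-scale error rate 0.01, about one candidate
    variant per 200 bp.
    """

    rng_seed: int = 0
    n_chrom: int = 1
    chrom_length: int = 100_000
    variant_rate: float = 1 / 200
    causal_regions: tuple[Region, ...] = ()
    mean_depth: float = 55.0
    error_rate: float = 0.01
    background_fixed_weight: float = 0.6  # share of fixed-reference sites
    missing_rate: float = 0.0
    low_gq_rate: float = 0.0   # share of sites forced below the GQ filter
    indel_fraction: float = 0.1
    depth_model: str = "poisson"  # or "constant"
    depth_multipliers: tuple[tuple[Region, float], ...] = ()
    emit_monomorphic: bool = False
    pool_names: tuple[str, str] = ("CBDA", "THCVA")
    # the first pool phenotypically matches the reference: causal sites have
    # true AF 0 there and 1 in the second pool

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error rate must satisfy 0 <= E < 0.5")
        if self.depth_model not in ("poisson", "constant"):
            raise ValueError("depth_model must be 'poisson' or 'constant'")
        for region in self.causal_regions:
            if not (1 <= region.start <= region.end <= self.chrom_length):
                raise ValueError(f"causal region out of bounds: {region}")
        for a in self.causal_regions:
            for b in self.causal_regions:
                if a is not b and a.overlaps(b.chrom, b.start, b.end):
                    raise ValueError("causal regions must not overlap")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


@dataclass
class TruthSet:
    """Ground truth of one simulation run."""

    causal_regions: tuple[Region, ...]
    sites: pd.DataFrame  # chrom, pos, true_af_a, true_af_b, classification

    def write(self, bed_path: str | Path, tsv_path: str | Path) -> None:
        with open(bed_path, "w") as fh:
            for region in self.causal_regions:
                fh.write(f"{region.chrom}\t{region.start - 1}\t{region.end}\tcausal\n")
        self.sites.to_csv(tsv_path, sep="\t", index=False)


def _gq_from_depth(depth: np.ndarray) -> np.ndarray:
    """Deterministic saturating depth->GQ map, capped at 99.

    A stand-in for genotype-likelihood-based quality that is monotone in
    depth and exercises the GQ >= 20 filter at low coverage.
    """
    return np.minimum(99, 3 * depth).astype(int)


def _call_genotype(alt: int, informative: int) -> tuple[int, int] | None:
    """Naive frequency-based diploid-style pool genotype call."""
    if informative == 0:
        return None
    frac = alt / informative
    if frac < 0.25:
        return (0, 0)
    if frac > 0.75:
        return (1, 1)
    return (0, 1)


def simulate_pools(
    config: SimulationConfig,
) -> tuple[list[PooledVariant], TruthSet]:
    """Simulate a joint two-pool variant set with ground truth.

    Fully reproducible from ``config.rng_seed``; the same config yields an
    identical variant list (and, via :func:`write_vcf`, a byte-identical
    VCF).
    """
    rng = np.random.default_rng(config.rng_seed)
    variants: list[PooledVariant] = []
    truth_rows: list[dict] = []
    pool_a, pool_b = config.pool_names

    for chrom in config.chrom_names():
        n_sites = rng.binomial(config.chrom_length, config.variant_rate)
        positions = np.sort(
            rng.choice(config.chrom_length, size=n_sites, replace=False) + 1
        )
        for pos in positions:
            pos = int(pos)
            causal = any(r.contains(chrom, pos) for r in config.causal_regions)
            if causal:
                p_a, p_b = 0.0, 1.0
                classification = "causal-fixed"
            else:
                if rng.random() < config.background_fixed_weight:
                    p = 0.0
                else:
                    p = rng.random()
                p_a = p_b = p
                classification = "background"

            mult = 1.0
            for region, m in config.depth_multipliers:
                if region.contains(chrom, pos):
                    mult = m
                    break
            mean_d = config.mean_depth * mult
            if config.depth_model == "poisson":
                d_a = int(rng.poisson(mean_d))
                d_b = int(rng.poisson(mean_d))
            else:
                d_a = d_b = int(round(mean_d))

            e = config.error_rate
            alt_a = int(rng.binomial(d_a, p_a * (1 - e) + (1 - p_a) * e)) if d_a else 0
            alt_b = int(rng.binomial(d_b, p_b * (1 - e) + (1 - p_b) * e)) if d_b else 0

            gt_a = _call_genotype(alt_a, d_a)
            gt_b = _call_genotype(alt_b, d_b)
            if not config.emit_monomorphic:
                # a joint caller only reports sites with non-reference evidence
                called = [gt for gt in (gt_a, gt_b) if gt is not None]
                if not called or all(gt == (0, 0) for gt in called):
                    continue

            gq_a = int(_gq_from_depth(np.array([d_a]))[0])
            gq_b = int(_gq_from_depth(np.array([d_b]))[0])
            if config.low_gq_rate and rng.random() < config.low_gq_rate:
                if rng.random() < 0.5:
                    gq_a = int(rng.integers(0, 20))
                else:
                    gq_b = int(rng.integers(0, 20))
            if config.missing_rate and rng.random() < config.missing_rate:
                if rng.random() < 0.5:
                    gt_a = None
                else:
                    gt_b = None

            ref, alt = _draw_alleles(rng, config.indel_fraction)
            samples = {
                pool_a: PoolSample(ref_count=d_a - alt_a, alt_count=alt_a,
                                   depth=d_a, gq=gq_a, genotyped=gt_a is not None),
                pool_b: PoolSample(ref_count=d_b - alt_b, alt_count=alt_b,
                                   depth=d_b, gq=gq_b, genotyped=gt_b is not None),
            }
            variants.append(PooledVariant(
                chrom=chrom, pos=pos, ref_allele=ref, alt_alleles=(alt,),
                samples=samples,
            ))
            truth_rows.append({
                "chrom": chrom, "pos": pos,
                "true_af_a": p_a, "true_af_b": p_b,
                "classification": classification,
            })

    truth = TruthSet(
        causal_regions=config.causal_regions,
        sites=pd.DataFrame(
            truth_rows,
            columns=["chrom", "pos", "true_af_a", "true_af_b", "classification"],
        ),
    )
    return variants, truth


def _draw_alleles(rng: np.random.Generator, indel_fraction: float) -> tuple[str, str]:
    i = int(rng.integers(0, 4))
    ref = _BASES[i]
    if rng.random() < indel_fraction:
        # single-base insertion: length-changing alternative allele
        extra = _BASES[int(rng.integers(0, 4))]
        return ref, ref + extra
    alt = _BASES[(i + 1 + int(rng.integers(0, 3))) % 4]
    return ref, alt


def write_vcf(
    variants: Sequence[PooledVariant],
    path: str | Path,
    config: SimulationConfig,
) -> None:
    """Write variants as a plain-text, bgzip-compatible VCF 4.2 file."""
    contigs = "".join(
        f"##contig=<ID={c},length={config.chrom_length}>\n"
        for c in config.chrom_names()
    )
    pool_a, pool_b = config.pool_names
    with open(path, "w") as fh:
        fh.write(VCF_HEADER_TEMPLATE.format(
            contigs=contigs, sample_a=pool_a, sample_b=pool_b))
        for v in variants:
            fields = [
                v.chrom, str(v.pos), ".", v.ref_allele, ",".join(v.alt_alleles),
                ".", "PASS", "NS=2", "GT:AD:DP:GQ",
            ]
            for name in (pool_a, pool_b):
                s = v.samples[name]
                gt = _format_gt(s, v)
                fields.append(f"{gt}:{s.ref_count},{s.alt_count}:{s.depth}:{s.gq}")
            fh.write("\t".join(fields) + "\n")


def _format_gt(sample: PoolSample, variant: PooledVariant) -> str:
    if not sample.genotyped:
        return "./."
    call = _call_genotype(sample.alt_count, sample.informative)
    if call is None:
        return "./."
    return f"{call[0]}/{call[1]}"


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# chemotype panel simulation


@dataclass(frozen=True)
class ChemotypeMixture:
    """Distribution parameters of the simulated chemotype panel.

    The dicyclic axis mixes low / intermediate / high Beta modes; the
    C3-alkyl axis mixes a dominant low-C3 mode with a high-C3 minority.
    Planted extremes draw from narrow joint ranges typical of real extreme
    pools (high-dicyclic pool: dicyclic ~94-97%, C3 ~0.5-0.9%; high-C3
    pool: C3 ~65-93%, dicyclic ~0.1-2.5%).
    """

    dicyclic_weights: tuple[float, float, float] = (0.2, 0.2, 0.6)
    dicyclic_low: tuple[float, float] = (1.5, 12.0)
    dicyclic_mid: tuple[float, float] = (8.0, 8.0)
    dicyclic_high: tuple[float, float] = (20.0, 4.0)
    c3_low: tuple[float, float] = (3.0, 40.0)
    c3_high: tuple[float, float] = (6.0, 8.0)
    c3_high_weight: float = 0.08
    pool_a_dicyclic_range: tuple[float, float] = (0.943, 0.971)
    pool_a_c3_range: tuple[float, float] = (0.005, 0.009)
    pool_b_dicyclic_range: tuple[float, float] = (0.001, 0.025)
    pool_b_c3_range: tuple[float, float] = (0.646, 0.929)

    def __post_init__(self) -> None:
        if abs(sum(self.dicyclic_weights) - 1.0) > 1e-9:
            raise ValueError("dicyclic mixture weights must sum to 1")


def simulate_chemotypes(
    n: int = 711,
    n_extreme_per_pool: int = 70,
    rng_seed: int = 0,
    mixture: ChemotypeMixture = ChemotypeMixture(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a chemotype panel with planted joint-extreme individuals.

    Returns ``(table, truth)``: ``table`` has one row per plant with the
    eight analyte concentrations (mg/g fresh weight); ``truth`` labels each
    plant ``pool_a_extreme`` / ``pool_b_extreme`` / ``background`` and
    records the drawn fractions. Concentrations are back-calculated from the
    drawn (dicyclic, c3) fractions via the multiplicative factorisation of
    the eight analytes, so fraction computation inverts the draw exactly.
    """
    if 2 * n_extreme_per_pool > n:
        raise ValueError("planted extremes exceed panel size")
    rng = np.random.default_rng(rng_seed)
    n_background = n - 2 * n_extreme_per_pool

    labels = (["pool_a_extreme"] * n_extreme_per_pool
              + ["pool_b_extreme"] * n_extreme_per_pool
              + ["background"] * n_background)
    dicyclic = np.empty(n)
    c3 = np.empty(n)

    sl = slice(0, n_extreme_per_pool)
    dicyclic[sl] = rng.uniform(*mixture.pool_a_dicyclic_range, n_extreme_per_pool)
    c3[sl] = rng.uniform(*mixture.pool_a_c3_range, n_extreme_per_pool)
    sl = slice(n_extreme_per_pool, 2 * n_extreme_per_pool)
    dicyclic[sl] = rng.uniform(*mixture.pool_b_dicyclic_range, n_extreme_per_pool)
    c3[sl] = rng.uniform(*mixture.pool_b_c3_range, n_extreme_per_pool)

    comp = rng.choice(3, size=n_background, p=mixture.dicyclic_weights)
    params = (mixture.dicyclic_low, mixture.dicyclic_mid, mixture.dicyclic_high)
    bg_dicyclic = np.array([
        rng.beta(*params[c]) for c in comp
    ])
    high_c3 = rng.random(n_background) < mixture.c3_high_weight
    bg_c3 = np.where(
        high_c3,
        rng.beta(*mixture.c3_high, n_background),
        rng.beta(*mixture.c3_low, n_background),
    )
    dicyclic[2 * n_extreme_per_pool:] = bg_dicyclic
    c3[2 * n_extreme_per_pool:] = bg_c3

    total = rng.uniform(1.0, 20.0, n)          # mg/g fresh weight
    acid_fraction = rng.uniform(0.85, 0.98, n)  # acids dominate fresh tissue

    order = rng.permutation(n)
    width = len(str(n))
    rows = []
    truth_rows = []
    for out_idx, i in enumerate(order):
        plant_id = f"plant{out_idx + 1:0{width}d}"
        conc = _fractions_to_concentrations(
            dicyclic[i], c3[i], total[i], acid_fraction[i]
        )
        rows.append({"plant_id": plant_id, **conc})
        truth_rows.append({
            "plant_id": plant_id, "label": labels[i],
            "dicyclic": dicyclic[i], "c3_alkyl": c3[i],
        })
    table = pd.DataFrame(rows, columns=["plant_id", *ANALYTES])
    truth = pd.DataFrame(truth_rows,
                         columns=["plant_id", "label", "dicyclic", "c3_alkyl"])
    return table, truth


def _fractions_to_concentrations(
    dicyclic: float, c3: float, total: float, acid_fraction: float
) -> dict[str, float]:
    """Invert the fraction computation: analytes factorise multiplicatively.

    Each analyte is (cyclisation class) x (alkyl class) x (acid/neutral):
    e.g. CBDVA = dicyclic * C3 * acid, THC = tricyclic * C5 * neutral.
    """
    d, t = dicyclic, 1.0 - dicyclic
    p3, p5 = c3, 1.0 - c3
    a, nn = acid_fraction, 1.0 - acid_fraction
    return {
        "CBDVA": total * d * p3 * a,
        "THCVA": total * t * p3 * a,
        "CBDA": total * d * p5 * a,
        "THCA": total * t * p5 * a,
        "CBDV": total * d * p3 * nn,
        "THCV": total * t * p3 * nn,
        "CBD": total * d * p5 * nn,
        "THC": total * t * p5 * nn,
    }
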