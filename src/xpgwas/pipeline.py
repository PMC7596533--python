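"""End-to-end orchestration: VCF -> hard filter -> AFe -> band -> intervals.

``run_all`` executes the full scan with one config and writes a manifest
recording parameters, per-stage record tallies (raw = survivors + removals
at every stage) and output checksums, so a re-run with the same config is
verifiably identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .intervals import (
    IntervalParams,
    detect_intervals,
    interval_summary,
    intervals_to_dataframe,
    report_interval_variants,
    write_intervals_bed,
    write_plot_table,
)
from .pool_afe import (
    AFeRecord,
    FilterParams,
    compute_afe_table,
    coverage_band_filter,
    hard_filter,
    mean_informative_depth,
    read_pooled_vcf,
    write_afe_tsv,
)
from .stitch import LiftoverTable
from .synthetic import file_checksum

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, pool naming and stage parameters for one pipeline run."""

    vcf: str
    out_dir: str
    pool_names: tuple[str, str] = ("CBDA", "THCVA")
    matching_pool: str | None = None  # defaults to the first pool name
    filter_params: FilterParams = field(default_factory=FilterParams)
    interval_params: IntervalParams = field(default_factory=IntervalParams)
    liftover_tsv: str | None = None
    mean_depths: tuple[float, float] | None = None

    def resolved_interval_params(self) -> IntervalParams:
        match = self.matching_pool or self.pool_names[0]
        if match not in self.pool_names:
            raise ValueError(
                f"matching_pool {match!r} is not one of {self.pool_names}")
        which = "a" if match == self.pool_names[0] else "b"
        if self.interval_params.matching_pool != which:
            from dataclasses import replace
            return replace(self.interval_params, matching_pool=which)
        return self.interval_params

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        fp = FilterParams(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in data.get("filter_params", {}).items()
        })
        ip = IntervalParams(**data.get("interval_params", {}))
        return cls(
            vcf=data["vcf"],
            out_dir=data["out_dir"],
            pool_names=tuple(data.get("pool_names", ("CBDA", "THCVA"))),
            matching_pool=data.get("matching_pool"),
            filter_params=fp,
            interval_params=ip,
            liftover_tsv=data.get("liftover_tsv"),
            mean_depths=tuple(data["mean_depths"]) if data.get("mean_depths") else None,
        )


def run_all(config: RunConfig) -> dict:
    """Run the full scan; write outputs and return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iparams = config.resolved_interval_params()

    variants = read_pooled_vcf(config.vcf, config.pool_names)
    n_raw = len(variants)
    logger.info("read %d variant records from %s", n_raw, config.vcf)

    survivors, tally = hard_filter(variants, config.filter_params)
    logger.info("hard filter: %d/%d pass (%s)", len(survivors), n_raw, dict(tally))

    afe_records = compute_afe_table(survivors, config.pool_names)
    n_zero_informative = len(survivors) - len(afe_records)

    banded: list[AFeRecord] = coverage_band_filter(
        afe_records, config.mean_depths, config.filter_params
    )
    logger.info("coverage band: %d/%d pass", len(banded), len(afe_records))

    liftover = (LiftoverTable.from_tsv(config.liftover_tsv)
                if config.liftover_tsv else None)
    intervals = detect_intervals(banded, iparams, liftover=liftover)
    summary = interval_summary(intervals)
    logger.info("detected %d intervals", summary["count"])

    reported = []
    for i, iv in enumerate(intervals, start=1):
        for rec in report_interval_variants(iv, banded, iparams):
            reported.append({
                "interval": i, "chrom": rec.chrom, "pos": rec.pos,
                "afe_a": rec.afe_a, "afe_b": rec.afe_b,
                "delta": rec.delta, "coverage": rec.coverage,
            })

    paths = {
        "afe_tsv": out / "afe.tsv",
        "intervals_bed": out / "intervals.bed",
        "intervals_tsv": out / "intervals.tsv",
        "variant_report_tsv": out / "interval_variants.tsv",
        "plot_table_tsv": out / "delta_track.tsv",
        "summary_json": out / "summary.json",
    }
    write_afe_tsv(banded, paths["afe_tsv"])
    write_intervals_bed(intervals, paths["intervals_bed"])
    intervals_to_dataframe(intervals).to_csv(
        paths["intervals_tsv"], sep="\t", index=False)
    import pandas as pd
    pd.DataFrame(
        reported,
        columns=["interval", "chrom", "pos", "afe_a", "afe_b", "delta", "coverage"],
    ).to_csv(paths["variant_report_tsv"], sep="\t", index=False)
    write_plot_table(banded, paths["plot_table_tsv"])
    paths["summary_json"].write_text(json.dumps(summary, indent=2) + "\n")

    mean_depths = (mean_informative_depth(afe_records) if afe_records
                   else (None, None))
    manifest = {
        "version": __version__,
        "config": {
            "vcf": config.vcf,
            "pool_names": list(config.pool_names),
            "matching_pool": config.matching_pool or config.pool_names[0],
            "filter_params": _jsonable(asdict(config.filter_params)),
            "interval_params": _jsonable(asdict(iparams)),
        },
        "stages": {
            "raw_records": n_raw,
            "hard_filter": {"pass": tally["pass"],
                            "removed": {k: tally[k] for k in tally
                                        if k != "pass"}},
            "afe": {"records": len(afe_records),
                    "zero_informative_skipped": n_zero_informative,
                    "mean_informative_depth": list(mean_depths)},
            "coverage_band": {"pass": len(banded),
                              "removed": len(afe_records) - len(banded)},
            "intervals": summary,
            "reported_variants": len(reported),
        },
        "outputs": {
            name: {"path": str(p), "sha256": file_checksum(p)}
            for name, p in paths.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _jsonable(d: dict) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else
                dict(v) if isinstance(v, dict) else v)
            for k, v in d.items()}
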