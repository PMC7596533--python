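"""Cannabinoid chemotype fractions and extreme-pool construction.

A plant's chemotype is summarised on two axes computed from the fresh-weight
concentrations of eight cannabinoids:

* cyclisation — dicyclic (CBD-type) vs tricyclic (THC-type) resorcinyl core;
* alkyl side chain — C3 (propyl, varin) vs C5 (pentyl) homologs.

Each fraction is the share of total cannabinoid content, so the two axes are
complementary partitions: ``dicyclic + tricyclic == 1`` and
``c3_alkyl + c5_alkyl == 1`` whenever the total is positive.

Extreme-phenotype pools are the two disjoint sets of plants most extreme at
opposite corners of the (dicyclic, c3_alkyl) plane — e.g. a high-dicyclic /
low-C3 "CBDA" pool against a low-dicyclic / high-C3 "THCVA" pool.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: The eight analytes, fresh-weight concentrations of which define a chemotype.
ANALYTES: tuple[str, ...] = (
    "CBDVA", "THCVA", "CBDA", "THCA", "CBDV", "THCV", "CBD", "THC",
)

DICYCLIC_ANALYTES = frozenset({"CBDVA", "CBDA", "CBDV", "CBD"})
TRICYCLIC_ANALYTES = frozenset({"THCVA", "THCA", "THCV", "THC"})
C3_ALKYL_ANALYTES = frozenset({"CBDVA", "THCVA", "CBDV", "THCV"})
C5_ALKYL_ANALYTES = frozenset({"CBDA", "THCA", "CBD", "THC"})


class NoMeasurableCannabinoidsError(ValueError):
    """Raised when a plant's total cannabinoid content is zero.

    Fractions are undefined for such plants; callers exclude them (logged).
    """


@dataclass(frozen=True)
class CannabinoidProfile:
    """One plant's analyte concentrations (mass/mass fresh weight)."""

    plant_id: str
    conc: Mapping[str, float]
    accession_id: str | None = None

    def __post_init__(self) -> None:
        for analyte in ANALYTES:
            if self.conc.get(analyte, 0.0) < 0:
                raise ValueError(
                    f"negative concentration for {analyte} in plant {self.plant_id}"
                )

    @property
    def total(self) -> float:
        return sum(self.conc.get(a, 0.0) for a in ANALYTES)


@dataclass(frozen=True)
class ChemotypeFractions:
    """Chemotype summarised as complementary fraction pairs in [0, 1]."""

    dicyclic: float
    tricyclic: float
    c3_alkyl: float
    c5_alkyl: float


@dataclass(frozen=True)
class PoolAssignment:
    """Membership of one extreme pool, in rank order (most extreme first)."""

    label: str
    members: tuple[str, ...]
    n_panel: int

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("pool members must be unique")

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def selectivity(self) -> float:
        return selectivity(self.k, self.n_panel)


def compute_fractions(profile: CannabinoidProfile) -> ChemotypeFractions:
    """Compute the dicyclic/tricyclic and C3/C5-alkyl fractions of a profile.

    Raises
    ------
    NoMeasurableCannabinoidsError
        If the plant's total cannabinoid content is zero.
    """
    total = profile.total
    if total <= 0:
        raise NoMeasurableCannabinoidsError(
            f"plant {profile.plant_id}: no measurable cannabinoids"
        )
    get = lambda a: profile.conc.get(a, 0.0)  # noqa: E731
    dicyclic = sum(get(a) for a in DICYCLIC_ANALYTES) / total
    c3 = sum(get(a) for a in C3_ALKYL_ANALYTES) / total
    return ChemotypeFractions(
        dicyclic=dicyclic,
        tricyclic=1.0 - dicyclic,
        c3_alkyl=c3,
        c5_alkyl=1.0 - c3,
    )


def selectivity(k: int, n: int) -> float:
    """Pool size as a percentage of the phenotyped panel: ``100 * k / n``."""
    if n <= 0:
        raise ValueError("panel size must be positive")
    if not 0 < k <= n:
        raise ValueError(f"pool size k={k} must satisfy 0 < k <= n={n}")
    return 100.0 * k / n


def select_extreme_pools(
    profiles: Sequence[CannabinoidProfile],
    k: int,
    labels: tuple[str, str] = ("CBDA", "THCVA"),
) -> tuple[PoolAssignment, PoolAssignment]:
    """Construct the two chemotypically extreme pools of size ``k``.

    Pool A (``labels[0]``) collects the ``k`` plants most extreme for high
    dicyclic and low C3-alkyl fractions; pool B (``labels[1]``) the ``k``
    most extreme in the opposite corner. Plants are ordered by a composite
    score — the sum of the plant's rank on each axis (average ranks for
    ties) — with ties broken by ``plant_id``. Pool B is ranked after
    excluding pool A's members, so the pools are disjoint by construction.

    Plants whose total cannabinoid content is zero are excluded (logged)
    before ranking, since their fractions are undefined.
    """
    usable: list[tuple[str, ChemotypeFractions]] = []
    for profile in profiles:
        try:
            usable.append((profile.plant_id, compute_fractions(profile)))
        except NoMeasurableCannabinoidsError:
            logger.info("excluding plant %s: no measurable cannabinoids",
                        profile.plant_id)
    if len({pid for pid, _ in usable}) != len(usable):
        raise ValueError("duplicate plant_id in panel")
    n_panel = len(usable)
    if 2 * k > n_panel:
        raise ValueError(
            f"pools would overlap: 2k={2 * k} exceeds usable panel of {n_panel}"
        )

    ids = [pid for pid, _ in usable]
    dicyclic = [f.dicyclic for _, f in usable]
    c3 = [f.c3_alkyl for _, f in usable]
    # rank 1 = most extreme on that axis for pool A
    rank_dicyclic_desc = rankdata([-d for d in dicyclic], method="average")
    rank_c3_asc = rankdata(c3, method="average")
    score_a = rank_dicyclic_desc + rank_c3_asc

    order_a = sorted(range(n_panel), key=lambda i: (score_a[i], ids[i]))
    pool_a = tuple(ids[i] for i in order_a[:k])
    taken = set(pool_a)
    # the pool-B ordering is the reverse composite (low dicyclic, high c3)
    order_b = sorted(
        (i for i in range(n_panel) if ids[i] not in taken),
        key=lambda i: (-score_a[i], ids[i]),
    )
    pool_b = tuple(ids[i] for i in order_b[:k])

    return (
        PoolAssignment(label=labels[0], members=pool_a, n_panel=n_panel),
        PoolAssignment(label=labels[1], members=pool_b, n_panel=n_panel),
    )


# ---------------------------------------------------------------------------
# table I/O


def read_chemotype_table(
    path: str | Path,
    analyte_columns: Mapping[str, str] | None = None,
    plant_id_column: str = "plant_id",
    accession_column: str = "accession_id",
    sep: str | None = None,
) -> list[CannabinoidProfile]:
    """Read a per-plant (or per-replicate) chemotype table (CSV or TSV).

    Replicate rows sharing a ``plant_id`` are averaged per analyte before
    profiles are built. ``analyte_columns`` maps canonical analyte names to
    the file's header names when they differ.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    colmap = {a: (analyte_columns or {}).get(a, a) for a in ANALYTES}
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ValueError(f"chemotype table missing analyte columns: {missing}")
    if plant_id_column not in df.columns:
        raise ValueError(f"chemotype table missing column {plant_id_column!r}")

    agg = {colmap[a]: "mean" for a in ANALYTES}
    has_accession = accession_column in df.columns
    if has_accession:
        agg[accession_column] = "first"
    grouped = df.groupby(plant_id_column, sort=True).agg(agg).reset_index()

    profiles = []
    for _, row in grouped.iterrows():
        profiles.append(CannabinoidProfile(
            plant_id=str(row[plant_id_column]),
            conc={a: float(row[colmap[a]]) for a in ANALYTES},
            accession_id=str(row[accession_column]) if has_accession else None,
        ))
    return profiles


def write_pool_tables(
    pools: tuple[PoolAssignment, PoolAssignment],
    profiles: Sequence[CannabinoidProfile],
    out_tsv: str | Path,
    out_json: str | Path | None = None,
) -> None:
    """Write pool membership TSV (plant, pool, rank, fractions) + JSON summary."""
    fractions = {}
    for p in profiles:
        try:
            fractions[p.plant_id] = compute_fractions(p)
        except NoMeasurableCannabinoidsError:
            continue
    rows = []
    for pool in pools:
        for rank, pid in enumerate(pool.members, start=1):
            f = fractions[pid]
            rows.append({
                "plant_id": pid, "pool": pool.label, "rank": rank,
                "dicyclic": f.dicyclic, "tricyclic": f.tricyclic,
                "c3_alkyl": f.c3_alkyl, "c5_alkyl": f.c5_alkyl,
            })
    pd.DataFrame(rows).to_csv(out_tsv, sep="\t", index=False)
    if out_json is not None:
        summary = {
            pool.label: {
                "k": pool.k,
                "n_panel": pool.n_panel,
                "selectivity_percent": round(pool.selectivity, 1),
            }
            for pool in pools
        }
        Path(out_json).write_text(json.dumps(summary, indent=2) + "\n")
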