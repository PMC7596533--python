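"""Scaffold stitching: concatenate unplaced scaffolds with N spacers.

Genome-wide scans are awkward over thousands of short unplaced scaffolds, so
these are concatenated into pseudomolecules ("super-scaffolds") with a
fixed-length run of ``N`` bases (default 550) between consecutive sources.
A liftover table records each source's offset so coordinates translate
bidirectionally; positions falling inside a spacer map to no source base.

Coordinates are 1-based inclusive throughout (VCF convention); BED exports
elsewhere in the package are 0-based half-open.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_SPACER_LEN = 550

#: Sentinel returned by :meth:`LiftoverTable.lift_to_source` for spacer bases.
SPACER = "spacer"


@dataclass(frozen=True)
class StitchPlan:
    """Which source scaffolds join into which super-scaffold, in order."""

    groups: tuple[tuple[str, tuple[str, ...]], ...]
    spacer_len: int = DEFAULT_SPACER_LEN

    def __post_init__(self) -> None:
        if self.spacer_len < 0:
            raise ValueError("spacer_len must be >= 0")
        seen: set[str] = set()
        for _, sources in self.groups:
            for sid in sources:
                if sid in seen:
                    raise ValueError(f"scaffold {sid!r} appears in more than one group")
                seen.add(sid)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StitchPlan":
        data = yaml.safe_load(Path(path).read_text())
        groups = tuple(
            (g["super_scaffold_id"], tuple(g["scaffolds"])) for g in data["groups"]
        )
        return cls(groups=groups, spacer_len=int(data.get("spacer_len", DEFAULT_SPACER_LEN)))

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "spacer_len": self.spacer_len,
            "groups": [
                {"super_scaffold_id": sid, "scaffolds": list(srcs)}
                for sid, srcs in self.groups
            ],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class LiftoverTable:
    """Offsets of source scaffolds within super-scaffolds.

    ``rows``: (super_scaffold_id, start_offset 0-based, source_scaffold_id,
    source_length), offsets strictly increasing within a super-scaffold.
    """

    rows: list[tuple[str, int, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_super: dict[str, list[tuple[int, str, int]]] = {}
        self._by_source: dict[str, tuple[str, int, int]] = {}
        for super_id, offset, source_id, length in self.rows:
            self._by_super.setdefault(super_id, []).append((offset, source_id, length))
            self._by_source[source_id] = (super_id, offset, length)
        for super_id, entries in self._by_super.items():
            offsets = [o for o, _, _ in entries]
            if offsets != sorted(offsets):
                raise ValueError(f"offsets not increasing in {super_id}")

    def super_length(self, super_id: str, spacer_len: int) -> int:
        entries = self._by_super[super_id]
        last_offset, _, last_len = entries[-1]
        return last_offset + last_len

    def lift_to_source(self, super_id: str, position: int) -> tuple[str, int] | str:
        """Map a 1-based super-scaffold position to (source_id, 1-based pos).

        Returns the :data:`SPACER` sentinel for positions inside a spacer.
        """
        entries = self._by_super.get(super_id)
        if entries is None:
            raise KeyError(f"unknown super-scaffold {super_id!r}")
        if position < 1 or position > self.super_length(super_id, 0):
            raise ValueError(f"position {position} out of range on {super_id}")
        offsets = [o for o, _, _ in entries]
        i = bisect_right(offsets, position - 1) - 1
        offset, source_id, length = entries[i]
        local = position - offset  # 1-based within source
        if local > length:
            return SPACER
        return source_id, local

    def lift_to_super(self, source_id: str, position: int) -> tuple[str, int]:
        """Map a 1-based source-scaffold position to (super_id, 1-based pos)."""
        try:
            super_id, offset, length = self._by_source[source_id]
        except KeyError:
            raise KeyError(f"unknown source scaffold {source_id!r}") from None
        if not 1 <= position <= length:
            raise ValueError(f"position {position} out of range on {source_id}")
        return super_id, offset + position

    def source_of(self, source_id: str) -> bool:
        return source_id in self._by_source

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("super_scaffold_id\tstart_offset\tsource_scaffold_id\tsource_length\n")
            for row in self.rows:
                fh.write("\t".join(map(str, row)) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LiftoverTable":
        rows = []
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                super_id, offset, source_id, length = line.rstrip("\n").split("\t")
                rows.append((super_id, int(offset), source_id, int(length)))
        return cls(rows=rows)


def default_plan(
    scaffold_ids: Sequence[str],
    chromosome_pattern: str = r"(?i)^chr",
    batch_size: int | None = None,
    spacer_len: int = DEFAULT_SPACER_LEN,
    super_prefix: str = "superscaffold",
) -> StitchPlan:
    """Group all non-chromosome scaffolds, in input order, into batches.

    Ids matching ``chromosome_pattern`` are left out of the plan (they pass
    through unstitched). ``batch_size=None`` puts every unplaced scaffold in
    a single super-scaffold.
    """
    pattern = re.compile(chromosome_pattern)
    unplaced = [sid for sid in scaffold_ids if not pattern.search(sid)]
    if not unplaced:
        return StitchPlan(groups=(), spacer_len=spacer_len)
    if batch_size is None:
        batch_size = len(unplaced)
    groups = []
    for b, start in enumerate(range(0, len(unplaced), batch_size), start=1):
        groups.append((f"{super_prefix}{b}", tuple(unplaced[start:start + batch_size])))
    return StitchPlan(groups=tuple(groups), spacer_len=spacer_len)


def stitch_scaffolds(
    sequences: Mapping[str, str],
    plan: StitchPlan,
) -> tuple[dict[str, str], LiftoverTable]:
    """Concatenate source scaffolds per the plan, with N spacers between.

    Returns the stitched sequences (super-scaffolds plus any input sequence
    not covered by the plan, unchanged) and the liftover table. Each
    super-scaffold's length is ``sum(source lengths) + (n-1) * spacer_len``.
    """
    planned: set[str] = set()
    rows: list[tuple[str, int, str, int]] = []
    out: dict[str, str] = {}
    spacer = "N" * plan.spacer_len
    for super_id, sources in plan.groups:
        parts = []
        offset = 0
        for sid in sources:
            if sid not in sequences:
                raise KeyError(f"scaffold {sid!r} named in plan is missing from input")
            seq = sequences[sid]
            rows.append((super_id, offset, sid, len(seq)))
            parts.append(seq)
            offset += len(seq) + plan.spacer_len
            planned.add(sid)
        out[super_id] = spacer.join(parts)
    for sid, seq in sequences.items():
        if sid not in planned:
            out[sid] = seq
    return out, LiftoverTable(rows=rows)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
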