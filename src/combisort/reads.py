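"""Turn per-bin read records into fragment- and pair-level count tables.

Reads either already carry candidate part ids per position (the simulator's
TSV interchange) or arrive as raw cassette sequence, in which case fragments
are identified by k-mers unique to one part across the catalog. A position
with no unique match, or with conflicting matches, degrades to missing —
mirroring the assay's inability to unambiguously assign some fragments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .parts import VARIABLE_CLASSES, ElementClass, PartsCatalog
from .simulate import BIN_LABELS, ReadSet

#: The four variable read positions, in cassette order.
POSITIONS: tuple[str, str, str, str] = ("enhancer", "promoter", "utr5", "utr3")

TallyLevel = Literal["single_element", "element_pair", "full_tuple"]


@dataclass
class BinCounts:
    """r_i,b read tallies with the per-bin totals needed for normalization.

    ``table`` is indexed by fragment key (part id, pair tuple or full tuple)
    with one column per bin; ``R_b`` counts all mapped reads per bin, complete
    or not; ``C_b`` is the sorted cell count per bin from the FACS record.
    """

    table: pd.DataFrame
    R_b: pd.Series
    C_b: pd.Series
    level: TallyLevel

    def __post_init__(self) -> None:
        if (self.table.values < 0).any():
            raise ValueError("negative read counts")


@dataclass
class ReadQC:
    """Completeness diagnostics over all mapped reads."""

    n_total: int
    n_complete: int
    per_position_missing: dict[str, float]

    @property
    def complete_fraction(self) -> float:
        return self.n_complete / self.n_total if self.n_total else float("nan")


class KmerIndex:
    """Maps k-mers unique to exactly one part to that part's id and class."""

    def __init__(self, catalog: PartsCatalog, k: int = 15):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        owner: dict[str, str | None] = {}
        for part in catalog.parts:
            seq = part.sequence
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if kmer in owner and owner[kmer] != part.part_id:
                    owner[kmer] = None  # shared between parts: uninformative
                else:
                    owner[kmer] = part.part_id
        self.unique = {km: pid for km, pid in owner.items() if pid is not None}
        self.part_class = {p.part_id: p.element_class for p in catalog.parts}

    def scan(self, sequence: str) -> dict[ElementClass, dict[str, int]]:
        """Per class: candidate part ids with the first match position."""
        hits: dict[ElementClass, dict[str, int]] = {}
        k = self.k
        for i in range(len(sequence) - k + 1):
            pid = self.unique.get(sequence[i : i + k])
            if pid is None:
                continue
            cls = self.part_class[pid]
            hits.setdefault(cls, {})
            if pid not in hits[cls]:
                hits[cls][pid] = i
        return hits


def assign_fragments(
    read: Mapping[str, object] | str,
    catalog: PartsCatalog | None = None,
    index: KmerIndex | None = None,
) -> tuple[str | None, str | None, str | None, str | None]:
    """Resolve a read to its ordered (enhancer, promoter, utr5, utr3) ids.

    ``read`` is either a mapping with per-position candidate ids (missing/NA
    allowed) or a raw cassette sequence. With raw sequence, each position is
    assigned by unique-k-mer vote: no candidate or >= 2 candidates -> missing;
    assignments violating cassette order along the sequence -> missing.
    """
    if isinstance(read, str):
        if index is None:
            if catalog is None:
                raise ValueError("raw-sequence assignment needs a catalog or KmerIndex")
            index = KmerIndex(catalog)
        hits = index.scan(read)
        assigned: list[str | None] = []
        positions: list[int | None] = []
        for cls in (ElementClass.ENHANCER, ElementClass.PROMOTER,
                    ElementClass.UTR5, ElementClass.UTR3):
            cands = hits.get(cls, {})
            if len(cands) == 1:
                ((pid, pos),) = cands.items()
                assigned.append(pid)
                positions.append(pos)
            else:
                assigned.append(None)
                positions.append(None)
        # order filter: surviving fragments must appear in cassette order;
        # a violation means the read is chimeric and cannot be trusted at all
        present = [p for p in positions if p is not None]
        if any(b <= a for a, b in zip(present, present[1:])):
            assigned = [None, None, None, None]
        return tuple(assigned)  # type: ignore[return-value]

    out = []
    for pos in POSITIONS:
        val = read.get(pos) if hasattr(read, "get") else read[pos]  # type: ignore[index]
        out.append(None if val is None or (isinstance(val, float) and np.isnan(val)) or val is pd.NA or val == "." else str(val))
    return tuple(out)  # type: ignore[return-value]


def read_qc(records: pd.DataFrame) -> ReadQC:
    """Completeness summary of an assigned read table."""
    present = records[list(POSITIONS)].notna()
    n_total = len(records)
    n_complete = int(present.all(axis=1).sum())
    missing = {pos: float(1.0 - present[pos].mean()) if n_total else 0.0 for pos in POSITIONS}
    return ReadQC(n_total=n_total, n_complete=n_complete, per_position_missing=missing)


def tally(
    reads: ReadSet | pd.DataFrame,
    cells_per_bin: Mapping[str, int] | pd.Series,
    level: TallyLevel = "single_element",
    pair: tuple[str, str] = ("enhancer", "promoter"),
    complete_only_totals: bool = False,
) -> tuple[BinCounts, ReadQC]:
    """Tally reads into r_i,b at the requested granularity.

    * ``single_element`` counts a read for every position it carries, so
      incomplete reads still inform the elements they do show.
    * ``element_pair`` counts reads where both positions of ``pair`` survive.
    * ``full_tuple`` counts only complete in-order four-fragment reads.

    R_b is all mapped reads per bin regardless of completeness (set
    ``complete_only_totals`` to restrict, for sensitivity analysis).
    """
    records = reads.records if isinstance(reads, ReadSet) else reads
    records = records.copy()
    unknown = set(records["bin"].unique()) - set(BIN_LABELS)
    if unknown:
        raise ValueError(f"unknown bin labels: {sorted(unknown)}")

    qc = read_qc(records)
    complete = records[list(POSITIONS)].notna().all(axis=1)
    totals_source = records[complete] if complete_only_totals else records
    r_b = totals_source.groupby("bin").size().reindex(BIN_LABELS, fill_value=0)

    if level == "single_element":
        frames = []
        for pos in POSITIONS:
            sub = records.loc[records[pos].notna(), ["bin", pos]]
            counts = (
                sub.groupby([pos, "bin"], observed=True)
                .size()
                .unstack("bin", fill_value=0)
                .reindex(columns=BIN_LABELS, fill_value=0)
            )
            counts.index = pd.MultiIndex.from_product(
                [[pos], counts.index], names=["element_class", "part_id"]
            )
            frames.append(counts)
        table = pd.concat(frames)
    elif level == "element_pair":
        a, b = pair
        sub = records.loc[records[a].notna() & records[b].notna(), ["bin", a, b]]
        table = (
            sub.groupby([a, b, "bin"], observed=True)
            .size()
            .unstack("bin", fill_value=0)
            .reindex(columns=BIN_LABELS, fill_value=0)
        )
        table.index.names = [a, b]
    elif level == "full_tuple":
        sub = records.loc[complete, ["bin", *POSITIONS]]
        table = (
            sub.groupby([*POSITIONS, "bin"], observed=True)
            .size()
            .unstack("bin", fill_value=0)
            .reindex(columns=BIN_LABELS, fill_value=0)
        )
        table.index.names = list(POSITIONS)
    else:
        raise ValueError(f"unknown tally level {level!r}")

    c_b = pd.Series(cells_per_bin).reindex(BIN_LABELS)
    if c_b.isna().any():
        raise ValueError("cells_per_bin must cover all four bins")
    counts = BinCounts(table=table.astype(int), R_b=r_b.astype(int), C_b=c_b.astype(int), level=level)
    return counts, qc


def counts_for_class(counts: BinCounts, element_class: ElementClass | str) -> BinCounts:
    """Restrict a single_element tally to one class, indexed by part id."""
    if counts.level != "single_element":
        raise ValueError("class restriction applies to single_element tallies")
    cls = ElementClass(element_class).value
    sub = counts.table.loc[cls]
    return BinCounts(table=sub, R_b=counts.R_b, C_b=counts.C_b, level="single_element")


def write_counts_tsv(counts: BinCounts, path) -> None:
    out = counts.table.copy()
    out.columns = [f"bin_{b}" for b in out.columns]
    out.to_csv(path, sep="\t")
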