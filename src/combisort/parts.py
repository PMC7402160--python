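"""Golden Gate parts, directed cassette assembly and combinatorial-space arithmetic.

The library design places five part classes in a fixed order —
enhancer (UAS), core promoter, 5' UTR, reporter, 3' UTR — joined by
Type-IIS (BsaI) assembly. Each junction retains a 4-nt scar whose sequence
is dictated by the class-specific overhang pairs, so parts can only combine
in the designed order even when ligated at random. The promoter part
additionally carries a 6-bp ``TATGCC`` insertion directly after the
enhancer/promoter scar, making the total spacer inserted between the
enhancer and the promoter core exactly 10 bp.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ElementClass(str, enum.Enum):
    """The five positional classes of a cassette, in assembly order."""

    ENHANCER = "enhancer"
    PROMOTER = "promoter"
    UTR5 = "utr5"
    REPORTER = "reporter"
    UTR3 = "utr3"


#: Assembly order of classes along the cassette (5' to 3').
CLASS_ORDER: tuple[ElementClass, ...] = (
    ElementClass.ENHANCER,
    ElementClass.PROMOTER,
    ElementClass.UTR5,
    ElementClass.REPORTER,
    ElementClass.UTR3,
)

#: The four variable classes that define the combinatorial space
#: (the reporter is fixed in every cassette).
VARIABLE_CLASSES: tuple[ElementClass, ...] = (
    ElementClass.ENHANCER,
    ElementClass.PROMOTER,
    ElementClass.UTR5,
    ElementClass.UTR3,
)

#: (upstream, downstream) 4-nt overhangs per class; adjacent classes share one.
CLASS_OVERHANGS: dict[ElementClass, tuple[str, str]] = {
    ElementClass.ENHANCER: ("AACG", "TGGC"),
    ElementClass.PROMOTER: ("TGGC", "TTCT"),
    ElementClass.UTR5: ("TTCT", "TATG"),
    ElementClass.REPORTER: ("TATG", "ATCC"),
    ElementClass.UTR3: ("ATCC", "GCTG"),
}

#: 6-bp insertion carried by every promoter part, placed right after the
#: TGGC junction so the enhancer/promoter spacer totals 10 bp.
PROMOTER_INSERTION = "TATGCC"

#: BsaI recognition site — the combinatorial-assembly enzyme. Parts carrying
#: this site internally (either strand) are destroyed during assembly.
BSAI_SITE = "GGTCTC"

_DNA_ALPHABET = frozenset("ACGT")


class AssemblyError(ValueError):
    """Raised when parts cannot be joined at a junction."""


def _validate_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{what}: sequence is empty")
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"{what}: non-ACGT characters {sorted(bad)}")
    return seq


@dataclass
class RegulatoryPart:
    """One cloned regulatory element with its class-specific overhangs.

    ``sequence`` is the part core only: overhangs and (for promoters) the
    ``TATGCC`` insertion are stored separately so junction arithmetic stays
    explicit.
    """

    part_id: str
    gene: str
    element_class: ElementClass
    sequence: str
    upstream_overhang: str = ""
    downstream_overhang: str = ""
    insertion_suffix: str = ""
    usable: bool = True

    def __post_init__(self) -> None:
        self.element_class = ElementClass(self.element_class)
        self.sequence = _validate_dna(self.sequence, self.part_id)
        up, down = CLASS_OVERHANGS[self.element_class]
        if not self.upstream_overhang:
            self.upstream_overhang = up
        if not self.downstream_overhang:
            self.downstream_overhang = down
        if (self.upstream_overhang, self.downstream_overhang) != (up, down):
            raise ValueError(
                f"{self.part_id}: overhangs ({self.upstream_overhang}, "
                f"{self.downstream_overhang}) do not match class "
                f"{self.element_class.value} ({up}, {down})"
            )
        if self.element_class is ElementClass.PROMOTER and not self.insertion_suffix:
            self.insertion_suffix = PROMOTER_INSERTION
        if self.element_class is not ElementClass.PROMOTER and self.insertion_suffix:
            raise ValueError(f"{self.part_id}: only promoter parts carry an insertion suffix")
        if has_internal_site(self):
            self.usable = False


def has_internal_site(part: "RegulatoryPart | str", recognition: str = BSAI_SITE) -> bool:
    """True iff ``recognition`` occurs in the part sequence on either strand."""
    if not recognition:
        raise ValueError("recognition site must be non-empty")
    seq = part if isinstance(part, str) else part.sequence
    seq = seq.upper()
    rc = str(Seq(recognition).reverse_complement()).upper()
    return recognition.upper() in seq or rc in seq


@dataclass
class PartsCatalog:
    """All cloned parts, indexed by id, with per-class bookkeeping."""

    parts: list[RegulatoryPart]

    def __post_init__(self) -> None:
        ids = [p.part_id for p in self.parts]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate part_ids: {dup}")
        pairs = [(p.gene, p.element_class) for p in self.parts]
        if len(pairs) != len(set(pairs)):
            raise ValueError("a (gene, element_class) pair appears more than once")
        self._by_id = {p.part_id: p for p in self.parts}

    def __len__(self) -> int:
        return len(self.parts)

    def __getitem__(self, part_id: str) -> RegulatoryPart:
        return self._by_id[part_id]

    def __contains__(self, part_id: str) -> bool:
        return part_id in self._by_id

    def by_class(
        self, element_class: ElementClass, usable_only: bool = False
    ) -> list[RegulatoryPart]:
        sel = [p for p in self.parts if p.element_class is ElementClass(element_class)]
        if usable_only:
            sel = [p for p in sel if p.usable]
        return sorted(sel, key=lambda p: p.part_id)

    def counts_by_class(self, usable_only: bool = False) -> dict[ElementClass, int]:
        return {c: len(self.by_class(c, usable_only)) for c in CLASS_ORDER}


def load_parts(parts_table: str | Path, sequences: str | Path) -> PartsCatalog:
    """Build a catalog from a parts TSV and a FASTA of part sequences.

    The TSV needs columns ``part_id``, ``gene``, ``element_class`` and may
    carry an optional ``usable`` column; the effective flag is the declared
    one AND-ed with the internal-BsaI screen. FASTA records are keyed by
    ``part_id``.
    """
    table = pd.read_csv(parts_table, sep="\t", dtype=str)
    required = {"part_id", "gene", "element_class"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"parts table lacks columns {sorted(missing_cols)}")
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(sequences), "fasta")}

    parts = []
    for row in table.itertuples(index=False):
        if row.part_id not in seqs:
            raise ValueError(f"no FASTA record for part_id {row.part_id!r}")
        try:
            cls = ElementClass(row.element_class)
        except ValueError:
            raise ValueError(
                f"unknown element_class {row.element_class!r} for part {row.part_id!r}"
            ) from None
        declared_usable = True
        if "usable" in table.columns and isinstance(row.usable, str):
            declared_usable = row.usable.strip().lower() not in {"false", "0", "no"}
        part = RegulatoryPart(
            part_id=row.part_id,
            gene=row.gene,
            element_class=cls,
            sequence=seqs[row.part_id],
        )
        if not declared_usable:
            part.usable = False
        parts.append(part)
    return PartsCatalog(parts)


def write_parts(catalog: PartsCatalog, parts_table: str | Path, sequences: str | Path) -> None:
    """Write a catalog back to the TSV + FASTA interchange format."""
    rows = [
        {
            "part_id": p.part_id,
            "gene": p.gene,
            "element_class": p.element_class.value,
            "usable": str(p.usable),
        }
        for p in catalog.parts
    ]
    pd.DataFrame(rows).to_csv(parts_table, sep="\t", index=False)
    records = [
        SeqRecord(Seq(p.sequence), id=p.part_id, description=p.gene) for p in catalog.parts
    ]
    SeqIO.write(records, str(sequences), "fasta")


@dataclass
class Cassette:
    """An assembled (enhancer, promoter, 5'UTR, reporter, 3'UTR) cassette.

    ``assembled_sequence`` spans enhancer start to 3'UTR end and contains the
    four internal junction scars; the outer AACG/GCTG overhangs that join the
    cassette to the vector are exposed via :meth:`flanked_sequence`.
    """

    enhancer_id: str
    promoter_id: str
    utr5_id: str
    reporter_id: str
    utr3_id: str
    assembled_sequence: str
    junction_table: list[tuple[int, str]] = field(default_factory=list)

    @property
    def tuple_ids(self) -> tuple[str, str, str, str]:
        """(enhancer, promoter, utr5, utr3) — the variable positions."""
        return (self.enhancer_id, self.promoter_id, self.utr5_id, self.utr3_id)

    def flanked_sequence(self) -> str:
        """Cassette with its outer vector-junction overhangs attached."""
        return "AACG" + self.assembled_sequence + "GCTG"

    def spacer_between(self, left_scar: str, downstream_insertion: str = "") -> int:
        """Length of inserted sequence at the junction starting with ``left_scar``."""
        return len(left_scar) + len(downstream_insertion)


def assemble_cassette(
    e: RegulatoryPart,
    p: RegulatoryPart,
    u5: RegulatoryPart,
    rep: RegulatoryPart,
    u3: RegulatoryPart,
) -> Cassette:
    """Join five parts in the designed order, recording every junction scar.

    The enhancer/promoter junction inserts exactly 10 bp: the 4-bp TGGC scar
    plus the promoter's 6-bp TATGCC suffix, the spacing reported as optimal
    for enhancer-driven transcription.
    """
    supplied = (e, p, u5, rep, u3)
    for part, expected in zip(supplied, CLASS_ORDER):
        if part.element_class is not expected:
            raise AssemblyError(
                f"position for {expected.value} received a "
                f"{part.element_class.value} part ({part.part_id})"
            )
        if not part.usable:
            raise AssemblyError(f"part {part.part_id} is not usable (internal site or uncloned)")
    for left, right in zip(supplied[:-1], supplied[1:]):
        if left.downstream_overhang != right.upstream_overhang:
            raise AssemblyError(
                f"overhang mismatch at {left.part_id}|{right.part_id}: "
                f"{left.downstream_overhang} vs {right.upstream_overhang}"
            )

    pieces: list[str] = []
    junctions: list[tuple[int, str]] = []
    pos = 0
    for i, part in enumerate(supplied):
        if i > 0:
            scar = part.upstream_overhang
            junctions.append((pos, scar))
            pieces.append(scar)
            pos += len(scar)
            if part.insertion_suffix:
                pieces.append(part.insertion_suffix)
                pos += len(part.insertion_suffix)
        pieces.append(part.sequence)
        pos += len(part.sequence)
    return Cassette(
        enhancer_id=e.part_id,
        promoter_id=p.part_id,
        utr5_id=u5.part_id,
        reporter_id=rep.part_id,
        utr3_id=u3.part_id,
        assembled_sequence="".join(pieces),
        junction_table=junctions,
    )


def enumerate_space(catalog: PartsCatalog, usable_only: bool = False) -> int:
    """Number of distinct cassettes: product of part counts over the four
    variable classes (the reporter is fixed).

    ``usable_only=False`` counts every cloned part — the design space
    (26 x 25 x 26 x 26 = 439,400 for the emulated catalog). ``usable_only=True``
    restricts to parts that survive assembly (internal-BsaI parts excluded),
    the space actually observable in sequencing.
    """
    counts = catalog.counts_by_class(usable_only=usable_only)
    total = 1
    for cls in VARIABLE_CLASSES:
        if counts[cls] == 0:
            raise ValueError(f"no {'usable ' if usable_only else ''}parts in class {cls.value}")
        total *= counts[cls]
    return total


def expected_coverage(n_clones: int, space_size: int) -> float:
    """Expected fraction of the design space present at least once when
    ``n_clones`` are drawn uniformly with replacement from ``space_size``
    designs: 1 - (1 - 1/N)^n (occupancy/coupon-collector expectation).
    """
    if space_size < 1:
        raise ValueError("space_size must be >= 1")
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    if n_clones == 0:
        return 0.0
    if space_size == 1:
        return 1.0
    # -expm1(n*log1p(-1/N)) is exact where (1-1/N)**n underflows
    return float(-math.expm1(n_clones * math.log1p(-1.0 / space_size)))
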