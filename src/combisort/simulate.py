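"""Synthetic Sort-seq data with the statistical structure the analysis assumes.

The generator emulates a combinatorial reporter library in yeast:

* a catalog of 26 genes contributing enhancer, promoter, 5'UTR and 3'UTR
  parts (the HIS3 core promoter was never cloned; the PHO5 and ADH1 enhancer
  parts carry internal BsaI sites and are destroyed during assembly);
* uniform-with-replacement library sampling over the usable cassette space;
* per-construct single-cell fluorescence that is log-normal, with the
  log-mean dominated by additive enhancer and promoter effects and much
  smaller UTR effects, and a subset of condition-inactive enhancers;
* 4-way FACS gating (none / low / medium / high) at fixed fluorescence
  boundaries;
* per-bin nanopore-style read sampling in which each of the four variable
  fragments is lost independently with a tunable dropout probability.

Every random draw flows from one integer seed through explicit
``numpy.random.Generator`` objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .parts import (
    BSAI_SITE,
    CLASS_ORDER,
    VARIABLE_CLASSES,
    ElementClass,
    PartsCatalog,
    RegulatoryPart,
    has_internal_site,
)

#: Bin labels in increasing fluorescence order.
BIN_LABELS: tuple[str, str, str, str] = ("none", "low", "medium", "high")

#: The 26 genes whose regulatory elements the emulated catalog carries.
DEFAULT_GENES: tuple[str, ...] = (
    "ACO1", "ADH1", "ADH2", "CCW12", "CDC19", "CUP1", "CWP2", "CYC1",
    "ENO2", "FBA1", "GAL1", "HIS3", "HXT7", "ICL1", "PDC1", "PGK1",
    "PHO5", "PMA1", "RPL18B", "RPL28", "SED1", "TDH3", "TEF1", "TEF2",
    "TPI1", "TSA1",
)

_PART_LENGTHS = {
    ElementClass.ENHANCER: 120,
    ElementClass.PROMOTER: 90,
    ElementClass.UTR5: 60,
    ElementClass.REPORTER: 150,
    ElementClass.UTR3: 80,
}


@dataclass(frozen=True)
class SortGates:
    """FACS gate boundaries defining the four expression fractions.

    Bins are half-open on fluorescence: [0,A1), [A1,A2), [A2,A3), [A3,inf).
    The defaults (1e2, 1e3, 1e4 arbitrary units) span two decades, a typical
    reporter dynamic range; the real instrument gates were never published.
    """

    boundaries: tuple[float, float, float] = (100.0, 1_000.0, 10_000.0)
    bin_labels: tuple[str, str, str, str] = BIN_LABELS

    def __post_init__(self) -> None:
        a1, a2, a3 = self.boundaries
        if not (0 < a1 < a2 < a3):
            raise ValueError(f"gate boundaries must satisfy 0 < A1 < A2 < A3, got {self.boundaries}")

    @property
    def log_boundaries(self) -> np.ndarray:
        return np.log(np.asarray(self.boundaries, dtype=float))

    def bin_index(self, fluorescence: np.ndarray) -> np.ndarray:
        """Index 0..3 of the gate each fluorescence value falls in."""
        return np.searchsorted(self.boundaries, np.asarray(fluorescence, float), side="right")

    def bin_probabilities(self, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        """Closed-form P(bin) for log-normal(log mu, sigma) cells, shape (..., 4)."""
        mu = np.atleast_1d(np.asarray(mu, float))
        sigma = np.atleast_1d(np.asarray(sigma, float))
        z = (self.log_boundaries[None, :] - np.log(mu)[:, None]) / sigma[:, None]
        cdf = stats.norm.cdf(z)
        probs = np.concatenate(
            [cdf[:, :1], np.diff(cdf, axis=1), 1.0 - cdf[:, -1:]], axis=1
        )
        return np.clip(probs, 0.0, 1.0)


@dataclass(frozen=True)
class EffectConfig:
    """Distributional settings for ground-truth element effects.

    Standard deviations are in log10 fluorescence units and encode the
    qualitative ordering seen in the assay: enhancers span the largest range,
    promoters modulate within it, UTRs contribute little. A fraction of
    enhancers is "inactive" under the simulated growth condition
    (glucose-repressed genes such as GAL1/ADH2/CUP1/ICL1) and receives a
    large negative offset. Cell-to-cell sigma is in natural-log units.
    """

    enhancer_sd: float = 0.8
    promoter_sd: float = 0.4
    utr5_sd: float = 0.08
    utr3_sd: float = 0.08
    inactive_enhancer_fraction: float = 0.15
    inactive_shift: float = -2.5
    interaction_sd: float = 0.0
    sigma_range: tuple[float, float] = (0.4, 0.8)
    baseline_mu: float = 1_000.0

    def class_sd(self, cls: ElementClass) -> float:
        return {
            ElementClass.ENHANCER: self.enhancer_sd,
            ElementClass.PROMOTER: self.promoter_sd,
            ElementClass.UTR5: self.utr5_sd,
            ElementClass.UTR3: self.utr3_sd,
        }[cls]

    def validate(self) -> None:
        for cls in VARIABLE_CLASSES:
            if self.class_sd(cls) < 0:
                raise ValueError(f"negative effect SD for {cls.value}")
        lo, hi = self.sigma_range
        if not (0 < lo <= hi):
            raise ValueError(f"sigma_range must be positive and ordered, got {self.sigma_range}")
        if self.baseline_mu <= 0:
            raise ValueError("baseline_mu must be positive")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _clean_random_dna(rng: np.random.Generator, length: int) -> str:
    # reject sequences that happen to contain the assembly enzyme site
    while True:
        seq = _random_dna(rng, length)
        if not has_internal_site(seq):
            return seq


def default_catalog(
    seed: int = 0,
    genes: Sequence[str] = DEFAULT_GENES,
    missing_promoters: Sequence[str] = ("HIS3",),
    bsai_blocked_enhancers: Sequence[str] = ("PHO5", "ADH1"),
) -> PartsCatalog:
    """The emulated parts catalog: 26 genes x 4 variable classes + 1 reporter.

    Sequences are synthetic placeholders (the real part boundaries are not
    published); the structural exclusions are faithful: the HIS3 promoter is
    absent, and the PHO5/ADH1 enhancer sequences contain an internal BsaI
    site so their ``usable`` flag is False.
    """
    rng = np.random.default_rng(seed)
    parts: list[RegulatoryPart] = []
    for gene in genes:
        for cls in VARIABLE_CLASSES:
            if cls is ElementClass.PROMOTER and gene in missing_promoters:
                continue
            seq = _clean_random_dna(rng, _PART_LENGTHS[cls])
            if cls is ElementClass.ENHANCER and gene in bsai_blocked_enhancers:
                # plant the recognition site mid-sequence
                mid = len(seq) // 2
                seq = seq[:mid] + BSAI_SITE + seq[mid + len(BSAI_SITE):]
            parts.append(
                RegulatoryPart(
                    part_id=f"{gene}_{cls.value}",
                    gene=gene,
                    element_class=cls,
                    sequence=seq,
                )
            )
    parts.append(
        RegulatoryPart(
            part_id="mRuby2_reporter",
            gene="mRuby2",
            element_class=ElementClass.REPORTER,
            sequence=_clean_random_dna(rng, _PART_LENGTHS[ElementClass.REPORTER]),
        )
    )
    return PartsCatalog(parts)


@dataclass
class GroundTruth:
    """True per-element effects and per-construct (mu, sigma).

    log10(mu) of a construct = log10(baseline) + the sum of its four element
    effects (+ an optional enhancer x promoter interaction). sigma is the
    cell-to-cell log-SD (natural log), built from a mid-range base plus small
    per-element offsets so it is deterministic per construct.
    """

    catalog: PartsCatalog
    config: EffectConfig
    seed: int
    part_ids: dict[ElementClass, list[str]]
    effects: dict[ElementClass, np.ndarray]
    sigma_offsets: dict[ElementClass, np.ndarray]
    interaction: np.ndarray | None = None

    @property
    def class_sizes(self) -> dict[ElementClass, int]:
        return {c: len(v) for c, v in self.part_ids.items()}

    def index_of(self, cls: ElementClass, part_id: str) -> int:
        return self.part_ids[cls].index(part_id)

    def element_effect(self, cls: ElementClass, part_id: str) -> float:
        """Additive log10 effect of one element."""
        return float(self.effects[ElementClass(cls)][self.index_of(cls, part_id)])

    def log10_mu(self, e, p, u5, u3) -> np.ndarray:
        """Vectorized log10 construct mean from part indices."""
        e = np.asarray(e, int); p = np.asarray(p, int)
        u5 = np.asarray(u5, int); u3 = np.asarray(u3, int)
        out = (
            np.log10(self.config.baseline_mu)
            + self.effects[ElementClass.ENHANCER][e]
            + self.effects[ElementClass.PROMOTER][p]
            + self.effects[ElementClass.UTR5][u5]
            + self.effects[ElementClass.UTR3][u3]
        )
        if self.interaction is not None:
            out = out + self.interaction[e, p]
        return out

    def mu(self, e, p, u5, u3) -> np.ndarray:
        return 10.0 ** self.log10_mu(e, p, u5, u3)

    def sigma(self, e, p, u5, u3) -> np.ndarray:
        lo, hi = self.config.sigma_range
        base = 0.5 * (lo + hi)
        raw = (
            base
            + self.sigma_offsets[ElementClass.ENHANCER][np.asarray(e, int)]
            + self.sigma_offsets[ElementClass.PROMOTER][np.asarray(p, int)]
            + self.sigma_offsets[ElementClass.UTR5][np.asarray(u5, int)]
            + self.sigma_offsets[ElementClass.UTR3][np.asarray(u3, int)]
        )
        return np.clip(raw, lo, hi)

    def construct_params(self, tuple_ids: tuple[str, str, str, str]) -> tuple[float, float]:
        """(mu, sigma) for one cassette given part ids."""
        idx = [
            self.index_of(cls, pid)
            for cls, pid in zip(VARIABLE_CLASSES, tuple_ids)
        ]
        return float(self.mu(*idx)), float(self.sigma(*idx))


def draw_effects(
    catalog: PartsCatalog,
    config: EffectConfig | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Draw ground-truth element effects for every usable part.

    Effects are normal per class with the configured SDs, median-centered per
    class so the median construct mean stays at the configured baseline
    (inside the gate range). A random subset of enhancers is shifted strongly
    negative to emulate condition-inactive genes.
    """
    config = config or EffectConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    part_ids: dict[ElementClass, list[str]] = {}
    effects: dict[ElementClass, np.ndarray] = {}
    sigma_offsets: dict[ElementClass, np.ndarray] = {}
    for cls in VARIABLE_CLASSES:
        ids = [p.part_id for p in catalog.by_class(cls, usable_only=True)]
        if not ids:
            raise ValueError(f"catalog has no usable parts of class {cls.value}")
        eff = rng.normal(0.0, config.class_sd(cls), size=len(ids))
        if cls is ElementClass.ENHANCER:
            n_inactive = int(round(config.inactive_enhancer_fraction * len(ids)))
            if n_inactive:
                idx = rng.choice(len(ids), size=n_inactive, replace=False)
                eff[idx] += config.inactive_shift
        eff -= np.median(eff)
        part_ids[cls] = ids
        effects[cls] = eff
        sigma_offsets[cls] = rng.normal(0.0, 0.02, size=len(ids))

    interaction = None
    if config.interaction_sd > 0:
        interaction = rng.normal(
            0.0,
            config.interaction_sd,
            size=(len(part_ids[ElementClass.ENHANCER]), len(part_ids[ElementClass.PROMOTER])),
        )
    return GroundTruth(
        catalog=catalog,
        config=config,
        seed=seed,
        part_ids=part_ids,
        effects=effects,
        sigma_offsets=sigma_offsets,
        interaction=interaction,
    )


@dataclass
class LibrarySample:
    """A multiset of sampled cassette tuples, as part-index arrays + counts."""

    truth: GroundTruth
    e_idx: np.ndarray
    p_idx: np.ndarray
    u5_idx: np.ndarray
    u3_idx: np.ndarray
    counts: np.ndarray

    @property
    def n_clones(self) -> int:
        return int(self.counts.sum())

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    def tuple_ids(self, i: int) -> tuple[str, str, str, str]:
        pid = self.truth.part_ids
        return (
            pid[ElementClass.ENHANCER][self.e_idx[i]],
            pid[ElementClass.PROMOTER][self.p_idx[i]],
            pid[ElementClass.UTR5][self.u5_idx[i]],
            pid[ElementClass.UTR3][self.u3_idx[i]],
        )


def simulate_library(truth: GroundTruth, n_clones: int, seed: int = 0) -> LibrarySample:
    """Sample ``n_clones`` cassettes uniformly with replacement from the
    usable combinatorial space."""
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = [truth.class_sizes[c] for c in VARIABLE_CLASSES]
    space = int(np.prod(sizes))
    codes = rng.integers(0, space, size=n_clones)
    uniq, counts = np.unique(codes, return_counts=True)
    # mixed-radix decode: code = ((e * nP + p) * nU5 + u5) * nU3 + u3
    n_e, n_p, n_u5, n_u3 = sizes
    u3 = uniq % n_u3
    rest = uniq // n_u3
    u5 = rest % n_u5
    rest //= n_u5
    p = rest % n_p
    e = rest // n_p
    return LibrarySample(truth, e, p, u5, u3, counts)


@dataclass
class SortedPopulation:
    """Per-construct cell counts in each of the four sorted fractions."""

    library: LibrarySample
    gates: SortGates
    cell_counts: np.ndarray  # (n_distinct, 4)

    @property
    def cells_per_bin(self) -> np.ndarray:
        """C_b: total sorted cells per bin."""
        return self.cell_counts.sum(axis=0)

    @property
    def total_cells(self) -> int:
        return int(self.cell_counts.sum())


def simulate_sort(
    truth: GroundTruth,
    library: LibrarySample,
    cells_per_construct: int,
    gates: SortGates | None = None,
    seed: int = 0,
) -> SortedPopulation:
    """Sort ``cells_per_construct`` cells per clone into the four gates.

    Each construct's cells are log-normal(log mu, sigma); the multinomial over
    the closed-form bin probabilities is equivalent to binning individual
    draws and conserves cell counts exactly.
    """
    if cells_per_construct < 1:
        raise ValueError("cells_per_construct must be >= 1")
    gates = gates or SortGates()
    rng = np.random.default_rng(seed)
    mu = library.truth.mu(library.e_idx, library.p_idx, library.u5_idx, library.u3_idx)
    sigma = library.truth.sigma(library.e_idx, library.p_idx, library.u5_idx, library.u3_idx)
    probs = gates.bin_probabilities(mu, sigma)
    probs /= probs.sum(axis=1, keepdims=True)
    n_cells = library.counts * cells_per_construct
    cell_counts = rng.multinomial(n_cells, probs)
    return SortedPopulation(library=library, gates=gates, cell_counts=cell_counts)


@dataclass
class ReadSet:
    """Per-bin sequencing reads over the four variable fragment positions.

    ``records`` has columns bin, enhancer, promoter, utr5, utr3; a dropped
    fragment is pandas NA. Surviving positions always keep cassette order.
    """

    records: pd.DataFrame
    reads_per_bin: pd.Series

    @property
    def n_reads(self) -> int:
        return len(self.records)


def simulate_reads(
    pop: SortedPopulation,
    reads: int | Sequence[int],
    dropout_rate: float = 0.0,
    seed: int = 0,
    proportional_to_cells: bool = True,
    read_shares: Sequence[float] | None = None,
) -> ReadSet:
    """Sample per-bin reads from the sorted cell pools with fragment dropout.

    ``reads`` may be a total (split across bins proportionally to sorted cell
    counts, or to ``read_shares`` to emulate disproportionate sequencing
    depth) or an explicit per-bin 4-vector. Each of the four fragment
    positions is lost independently with probability ``dropout_rate``.
    """
    if not (0 <= dropout_rate < 1):
        raise ValueError("dropout_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    c_b = pop.cells_per_bin.astype(float)

    if np.isscalar(reads):
        total = int(reads)
        if read_shares is not None:
            shares = np.asarray(read_shares, float)
        elif proportional_to_cells:
            shares = c_b
        else:
            shares = np.ones(4)
        shares = shares / shares.sum()
        r_b = np.floor(total * shares).astype(int)
        # largest-remainder rounding keeps the total exact
        remainder = total - r_b.sum()
        order = np.argsort(-(total * shares - r_b))
        r_b[order[:remainder]] += 1
    else:
        r_b = np.asarray(reads, int)
        if r_b.shape != (4,):
            raise ValueError("per-bin reads must be a length-4 vector")

    truth = pop.library.truth
    pid = truth.part_ids
    id_arrays = {
        "enhancer": np.asarray(pid[ElementClass.ENHANCER], dtype=object)[pop.library.e_idx],
        "promoter": np.asarray(pid[ElementClass.PROMOTER], dtype=object)[pop.library.p_idx],
        "utr5": np.asarray(pid[ElementClass.UTR5], dtype=object)[pop.library.u5_idx],
        "utr3": np.asarray(pid[ElementClass.UTR3], dtype=object)[pop.library.u3_idx],
    }

    frames = []
    realized = []
    for b, label in enumerate(pop.gates.bin_labels):
        n_req = int(r_b[b])
        if n_req == 0:
            realized.append(0)
            continue
        if c_b[b] == 0:
            warnings.warn(f"bin {label!r} holds no cells; 0 reads produced", stacklevel=2)
            realized.append(0)
            continue
        p = pop.cell_counts[:, b] / c_b[b]
        per_construct = rng.multinomial(n_req, p)
        reads_idx = np.repeat(np.arange(len(p)), per_construct)
        df = pd.DataFrame(
            {
                "bin": label,
                "enhancer": id_arrays["enhancer"][reads_idx],
                "promoter": id_arrays["promoter"][reads_idx],
                "utr5": id_arrays["utr5"][reads_idx],
                "utr3": id_arrays["utr3"][reads_idx],
            }
        )
        if dropout_rate > 0:
            drop = rng.random((len(df), 4)) < dropout_rate
            for j, col in enumerate(("enhancer", "promoter", "utr5", "utr3")):
                df.loc[drop[:, j], col] = pd.NA
        frames.append(df)
        realized.append(len(df))

    records = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["bin", "enhancer", "promoter", "utr5", "utr3"])
    )
    reads_per_bin = pd.Series(realized, index=list(pop.gates.bin_labels), name="R_b")
    return ReadSet(records=records, reads_per_bin=reads_per_bin)


def simulate_cytometry(
    truth: GroundTruth,
    tuple_ids: tuple[str, str, str, str],
    n_cells: int,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell fluorescence for one cassette: log-normal(log mu, sigma)."""
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    mu, sigma = truth.construct_params(tuple_ids)
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=np.log(mu), sigma=sigma, size=n_cells)


# ---------------------------------------------------------------------------
# text interchange
# ---------------------------------------------------------------------------

def write_reads_tsv(readset: ReadSet, path: str | Path) -> None:
    readset.records.to_csv(path, sep="\t", index=False, na_rep=".")


def read_reads_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    return df


def write_bins_tsv(pop: SortedPopulation, readset: ReadSet, path: str | Path) -> None:
    """Bin metadata: sorted cells C_b, mapped reads R_b, gate upper bound."""
    uppers = list(pop.gates.boundaries) + [np.inf]
    pd.DataFrame(
        {
            "bin": list(pop.gates.bin_labels),
            "C_b": pop.cells_per_bin,
            "R_b": readset.reads_per_bin.values,
            "gate_upper": uppers,
        }
    ).to_csv(path, sep="\t", index=False)


def read_bins_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_tsv(truth: GroundTruth, path: str | Path) -> None:
    """Element effects table for scoring recovered against true values."""
    rows = []
    for cls in VARIABLE_CLASSES:
        for pid, eff in zip(truth.part_ids[cls], truth.effects[cls]):
            rows.append(
                {"element_class": cls.value, "part_id": pid, "log10_effect": eff}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
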