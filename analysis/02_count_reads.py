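"""Tally the simulated reads into per-element and per-pair count tables.

Reads results/reads.tsv + results/bins.tsv from step 01, reports read QC
(completeness, per-position loss) and writes single-element and
enhancer-promoter pair count tables.
"""

import argparse
from pathlib import Path

import combisort as cs
from combisort.reads import write_counts_tsv
from combisort.simulate import read_bins_tsv, read_reads_tsv


def main(outdir: Path = Path("results")) -> None:
    records = read_reads_tsv(outdir / "reads.tsv")
    bins = read_bins_tsv(outdir / "bins.tsv").set_index("bin")
    cells = bins["C_b"].to_dict()

    single, qc = cs.tally(records, cells, level="single_element")
    pair, _ = cs.tally(records, cells, level="element_pair")

    print(f"{qc.n_total:,} mapped reads; {qc.complete_fraction:.1%} carry all four "
          "fragments in order")
    worst = max(qc.per_position_missing, key=qc.per_position_missing.get)
    print("per-position missing: "
          + ", ".join(f"{k} {v:.1%}" for k, v in qc.per_position_missing.items())
          + f" (worst: {worst})")

    write_counts_tsv(single, outdir / "counts_single.tsv")
    write_counts_tsv(pair, outdir / "counts_pair.tsv")
    print(f"wrote {len(single.table):,} element rows and {len(pair.table):,} "
          f"enhancer-promoter pair rows -> {outdir}/counts_*.tsv")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    main(ap.parse_args().outdir)
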