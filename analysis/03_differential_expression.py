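#!/usr/bin/env python
"""Per-stage differential expression between the two genotypes.

Screens every stage under both conditions with the replicate-free exact
conditional test and the p <= 0.05 plus two-fold-change rule, then
deduplicates calls across stages (the unique DE sets). Writes one TSV per
condition-stage plus union tables under results/tables/.
"""

import argparse
from pathlib import Path

from mirheat import (
    apply_expression_floor,
    make_contrast,
    normalize_cpm,
    read_counts,
    screen,
    unique_de_union,
    write_results,
)
from mirheat.diffexpr import called
from mirheat.io import STAGES


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    sim = args.outdir / "simulated"

    counts, design = read_counts(sim / "counts.tsv", sim / "sample_sheet.tsv")
    expr = apply_expression_floor(normalize_cpm(counts), 10.0)

    tables = {}
    for condition in ("NT", "HT"):
        per_stage = {}
        for stage in STAGES:
            res = screen(expr, counts, make_contrast(design, stage, condition))
            per_stage[stage] = res
            tables[f"de_{condition}_{stage}"] = res
            n_up = (res["call"] == "up").sum()
            n_down = (res["call"] == "down").sum()
            print(f"{condition} {stage}: {n_up} up, {n_down} down "
                  f"(of {len(res)} tested)")
        union = unique_de_union(per_stage)
        tables[f"de_union_{condition}"] = union
        print(f"{condition}: {len(union)} unique DE miRNAs across stages")

    write_results(tables, args.outdir / "tables")


if __name__ == "__main__":
    main()
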