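#!/usr/bin/env python
"""Integrate responsive miRNAs with target-gene DE calls and qPCR validation.

Joins each stage's responsive miRNAs to the predicted target pairs and the
gene-level DE table (flagging anti-correlated miRNA-target pairs), then
compares sequencing fold changes with 2^-ddCt qPCR estimates per assay and
reports the direction-agreement fraction.
"""

import argparse
from pathlib import Path

import pandas as pd

from mirheat import (
    classify,
    concordance_report,
    join_targets,
    read_counts,
    read_mature_fasta,
    run_stage_analysis,
    write_results,
)
from mirheat.families import family_of
from mirheat.integration import ddct_from_table, family_target_summary
from mirheat.io import STAGES, read_ct_table, read_gene_de_table, read_target_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    sim = args.outdir / "simulated"

    counts, design = read_counts(sim / "counts.tsv", sim / "sample_sheet.tsv")
    catalog = read_mature_fasta(sim / "mature.fa")
    targets = read_target_table(sim / "targets.tsv")
    gene_de = read_gene_de_table(sim / "gene_de.tsv")
    ct = read_ct_table(sim / "ct_values.tsv")

    responses = run_stage_analysis(counts, design, catalog)
    fam_map = family_of(classify(catalog))
    pairs = join_targets(
        {s: responses[s].responsive for s in STAGES}, targets, gene_de, fam_map
    )
    rollup = family_target_summary(pairs)
    n_anti = (pairs["relationship"] == "anti_correlated").sum()
    print(f"{len(pairs)} (miRNA, target) pairs at responsive stages; "
          f"{n_anti} anti-correlated")

    seq_fc, qpcr_fc = {}, {}
    for stage in STAGES:
        resp = responses[stage].responsive.set_index("mirna_id")
        for assay in ct["target_name"].unique():
            mirna, at_stage = assay.split("@")
            if at_stage != stage or mirna not in resp.index:
                continue
            seq_fc[assay] = float(resp.loc[mirna, "fold_change"])
            qpcr_fc[assay] = ddct_from_table(ct, assay).relative_expression
    report = concordance_report(pd.Series(seq_fc), pd.Series(qpcr_fc))
    print(f"qPCR vs sequencing direction agreement: "
          f"{report.attrs['agreement']:.2f} over {len(report)} assays")

    write_results(
        {"target_pairs": pairs, "family_targets": rollup, "qpcr_concordance": report},
        args.outdir / "tables",
        summary={"qpcr_agreement": report.attrs["agreement"]},
    )


if __name__ == "__main__":
    main()
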