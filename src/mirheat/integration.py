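"""Target-gene integration and qPCR relative quantification.

Responsive miRNAs are joined to externally predicted miRNA->gene target
pairs and to gene-level differential-expression calls; a pair where the
miRNA and its target move in opposite directions in the tolerant line is
flagged anti-correlated, the signature of active miRNA-mediated repression.
qPCR validation uses the comparative 2^-ddCt method against a single
reference assay per measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def join_targets(
    responsive_by_stage: dict[str, pd.DataFrame],
    target_table: pd.DataFrame,
    gene_de_table: pd.DataFrame,
    family_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Annotate each (responsive miRNA, predicted target) pair per stage.

    ``target_table`` has columns mirna_id, gene_id; ``gene_de_table`` has
    gene_id, stage, direction (in the tolerant line). Pairs whose gene has
    no DE call at the stage are kept as "unpaired". Target rows naming a
    miRNA that is not responsive at any stage are dropped (they are decoys
    or out-of-scope predictions).
    """
    gene_dir = {
        (r.gene_id, r.stage): r.direction for r in gene_de_table.itertuples(index=False)
    }
    rows = []
    for stage, responsive in responsive_by_stage.items():
        if not len(responsive):
            continue
        mir_dir = dict(zip(responsive["mirna_id"], responsive["call"]))
        for pair in target_table.itertuples(index=False):
            if pair.mirna_id not in mir_dir:
                continue
            mdir = mir_dir[pair.mirna_id]
            gdir = gene_dir.get((pair.gene_id, stage))
            if gdir is None:
                rel = "unpaired"
            elif gdir != mdir:
                rel = "anti_correlated"
            else:
                rel = "co_directional"
            rows.append(
                {
                    "stage": stage,
                    "mirna_id": pair.mirna_id,
                    "family_name": (family_map or {}).get(pair.mirna_id, pair.mirna_id),
                    "mirna_direction": mdir,
                    "gene_id": pair.gene_id,
                    "gene_direction": gdir if gdir is not None else "",
                    "relationship": rel,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "stage",
            "mirna_id",
            "family_name",
            "mirna_direction",
            "gene_id",
            "gene_direction",
            "relationship",
        ],
    )


def family_target_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    """Family -> target rollup: one row per (stage, family) with its genes."""
    if not len(pairs):
        return pd.DataFrame(columns=["stage", "family_name", "n_targets", "n_anti", "genes"])
    rows = []
    for (stage, fam), grp in pairs.groupby(["stage", "family_name"], sort=True):
        rows.append(
            {
                "stage": stage,
                "family_name": fam,
                "n_targets": grp["gene_id"].nunique(),
                "n_anti": int((grp["relationship"] == "anti_correlated").sum()),
                "genes": ";".join(sorted(grp["gene_id"].unique())),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DdctResult:
    """2^-ddCt relative expression with its replicate spread.

    delta_delta_ct = mean dCt(treatment) - mean dCt(control), where
    dCt = Ct(target) - Ct(reference) per sample; relative_expression is
    2^-ddCt (1 = no change). se_delta_delta_ct propagates the per-group
    standard errors of dCt.
    """

    delta_delta_ct: float
    relative_expression: float
    se_delta_delta_ct: float

    @property
    def fold_range(self) -> tuple[float, float]:
        lo = 2.0 ** -(self.delta_delta_ct + self.se_delta_delta_ct)
        hi = 2.0 ** -(self.delta_delta_ct - self.se_delta_delta_ct)
        return (lo, hi)


def _delta_ct(group: pd.DataFrame, label: str) -> np.ndarray:
    for col in ("ct_target", "ct_reference"):
        missing = group[col].isna()
        if missing.any():
            bad = group.loc[missing, "sample_id"].tolist()
            raise ValueError(f"{label}: missing {col} for samples {bad}")
    return (group["ct_target"] - group["ct_reference"]).to_numpy(dtype=float)


def ddct(treatment: pd.DataFrame, control: pd.DataFrame) -> DdctResult:
    """Comparative 2^-ddCt relative quantification between two groups.

    Each frame needs sample_id, ct_target, ct_reference columns with one row
    per replicate. Swapping the groups inverts the result (x -> 1/x).
    """
    if not len(treatment) or not len(control):
        raise ValueError("both treatment and control need >= 1 measurement")
    d_t = _delta_ct(treatment, "treatment")
    d_c = _delta_ct(control, "control")
    ddct_val = float(d_t.mean() - d_c.mean())
    se = float(
        np.sqrt(
            (d_t.std(ddof=1) ** 2 / len(d_t) if len(d_t) > 1 else 0.0)
            + (d_c.std(ddof=1) ** 2 / len(d_c) if len(d_c) > 1 else 0.0)
        )
    )
    return DdctResult(ddct_val, 2.0**-ddct_val, se)


def ddct_from_table(ct_table: pd.DataFrame, target_name: str) -> DdctResult:
    """Run ddct on one assay of a long-format Ct table (group in {treatment, control})."""
    sub = ct_table[ct_table["target_name"] == target_name]
    if not len(sub):
        raise ValueError(f"no measurements for assay {target_name!r}")
    return ddct(sub[sub["group"] == "treatment"], sub[sub["group"] == "control"])


def concordance_report(
    fold_changes_seq: pd.Series, fold_changes_qpcr: pd.Series
) -> pd.DataFrame:
    """Direction agreement between sequencing and qPCR fold changes.

    Both series map identifier -> fold change (ratio scale). Agreement is
    sign(log2 FC_seq) == sign(log2 FC_qpcr) per item; the overall agreement
    fraction is in ``attrs['agreement']``.
    """
    shared = sorted(set(fold_changes_seq.index) & set(fold_changes_qpcr.index))
    if not shared:
        raise ValueError("no overlapping identifiers between sequencing and qPCR")
    seq = np.log2(fold_changes_seq[shared].to_numpy(dtype=float))
    qp = np.log2(fold_changes_qpcr[shared].to_numpy(dtype=float))
    agree = np.sign(seq) == np.sign(qp)
    out = pd.DataFrame(
        {
            "item": shared,
            "log2fc_seq": seq,
            "log2fc_qpcr": qp,
            "direction_agrees": agree,
        }
    )
    out.attrs["agreement"] = float(agree.mean())
    return out
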