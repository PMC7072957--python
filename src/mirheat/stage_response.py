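"""Genotype-adjusted, stage-resolved screening for heat-responsive miRNA families.

The central procedure: at each anther developmental stage, miRNAs
differentially expressed between the tolerant and sensitive lines under heat
(HT) are screened, and those whose tolerant-vs-sensitive difference is
already present under control temperature (NT) — genotype-specific changes —
are removed. Surviving miRNAs are rolled up into families; each family's
abundance rate is its members' share of the total expression of all
responsive miRNAs at that stage, and families holding more than 10% of that
total are flagged as the stage's main regulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .abundance import ExpressionMatrix, apply_expression_floor, normalize_cpm
from .diffexpr import called, make_contrast, screen
from .families import classify, family_of
from .io import CountMatrix, DesignError, MiRNARecord, SampleDesign, STAGES

REMOVAL_MODES = ("same_direction", "any_de")


def remove_genotype_specific(
    de_ht: pd.DataFrame,
    de_nt: pd.DataFrame,
    mode: str = "same_direction",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split one stage's HT-DE calls into responsive and genotype-specific sets.

    ``de_ht``/``de_nt`` are screen results for the same stage under HT and NT.
    An HT-called miRNA is removed as genotype-specific when it is also
    NT-called — in the same direction (mode="same_direction", default: an
    HT-specific reversal still counts as a response) or in any direction
    (mode="any_de"). Returns (responsive, removed); the removed frame carries
    its NT call as evidence.
    """
    if mode not in REMOVAL_MODES:
        raise ValueError(f"unknown removal mode {mode!r}")
    ht_stages = set(de_ht.get("stage", pd.Series(dtype=str)))
    nt_stages = set(de_nt.get("stage", pd.Series(dtype=str)))
    if ht_stages and nt_stages and ht_stages != nt_stages:
        raise DesignError(
            f"stage mismatch between DE lists: HT {sorted(ht_stages)} vs NT {sorted(nt_stages)}"
        )
    ht_calls = called(de_ht)
    nt_dir = dict(zip(called(de_nt)["mirna_id"], called(de_nt)["call"]))
    if mode == "same_direction":
        removed_mask = ht_calls.apply(
            lambda r: nt_dir.get(r["mirna_id"]) == r["call"], axis=1
        )
    else:
        removed_mask = ht_calls["mirna_id"].isin(nt_dir)
    if not len(ht_calls):
        removed_mask = pd.Series(False, index=ht_calls.index)
    responsive = ht_calls[~removed_mask].copy()
    removed = ht_calls[removed_mask].copy()
    removed["nt_call"] = removed["mirna_id"].map(nt_dir)
    return responsive, removed


def family_abundance_rates(
    responsive: pd.DataFrame,
    expr: ExpressionMatrix,
    family_map: Mapping[str, str],
    stage_libraries: list[str],
) -> pd.Series:
    """Family shares (%) of total responsive-miRNA abundance at one stage.

    abundance(miRNA) = mean TPM over ``stage_libraries`` (the stage's HT
    libraries by default upstream); rate(family) = sum of its responsive
    members' abundance / sum over all responsive miRNAs x 100. Families with
    no responsive member are absent (not 0%); rates over represented
    families sum to 100%. An empty responsive set yields an empty series.
    """
    if not len(responsive):
        return pd.Series(dtype=float, name="abundance_rate_pct")
    mirnas = responsive["mirna_id"].tolist()
    missing = [m for m in mirnas if m not in expr.tpm.index]
    if missing:
        raise KeyError(f"responsive miRNAs absent from expression matrix: {missing}")
    abund = expr.tpm.loc[mirnas, stage_libraries].mean(axis=1)
    fams = pd.Series({m: family_map.get(m, m) for m in mirnas})
    total = abund.sum()
    if total <= 0:
        # all responsive miRNAs at zero abundance in these libraries
        return pd.Series(0.0, index=sorted(set(fams)), name="abundance_rate_pct")
    rates = abund.groupby(fams).sum() / total * 100.0
    rates.name = "abundance_rate_pct"
    return rates.sort_values(ascending=False, kind="mergesort")


def select_main_regulators(
    family_rates: pd.Series, main_threshold: float = 10.0
) -> list[str]:
    """Families whose abundance rate strictly exceeds the threshold (default 10%),
    best first. A family at exactly the threshold is excluded ("more than 10%")."""
    above = family_rates[family_rates > main_threshold]
    return above.sort_values(ascending=False, kind="mergesort").index.tolist()


def summarize_directions(
    responsive: pd.DataFrame,
    expr: ExpressionMatrix,
    family_map: Mapping[str, str],
    stage_libraries: list[str],
    high: float = 500.0,
) -> pd.DataFrame:
    """Per-family direction pattern among a stage's responsive members.

    A family with responsive members in both directions is "opposing";
    otherwise coherent_up/coherent_down. The dominant direction is the
    high-abundance member's (max TPM >= ``high`` over the stage libraries)
    when exactly such a member exists, else the direction of the most
    abundant member.
    """
    rows = []
    if not len(responsive):
        return pd.DataFrame(
            columns=["family_name", "pattern", "dominant_direction", "n_members"]
        )
    work = responsive.copy()
    work["family_name"] = work["mirna_id"].map(lambda m: family_map.get(m, m))
    peak = expr.tpm[stage_libraries].max(axis=1)
    for fam, grp in work.groupby("family_name", sort=True):
        dirs = set(grp["call"])
        pattern = (
            "opposing"
            if dirs == {"up", "down"}
            else ("coherent_up" if dirs == {"up"} else "coherent_down")
        )
        grp_peak = peak.reindex(grp["mirna_id"]).fillna(0.0)
        top = grp_peak.idxmax()
        dominant = grp.loc[grp["mirna_id"] == top, "call"].iloc[0]
        rows.append(
            {
                "family_name": fam,
                "pattern": pattern,
                "dominant_direction": dominant,
                "n_members": len(grp),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StageAnalysisConfig:
    """Knobs for the full per-stage pipeline (defaults are the screen's)."""

    alpha: float = 0.05
    fc_high: float = 2.0
    fc_low: float = 0.5
    pseudocount: float = 1.0
    tpm_floor: float = 10.0
    high_abundance: float = 500.0
    removal_mode: str = "same_direction"
    main_threshold: float = 10.0
    rate_condition: str = "HT"  # which libraries anchor abundance rates
    adjust: str | None = None


@dataclass
class StageResponse:
    """One stage's genotype-adjusted heat-response summary."""

    stage: str
    responsive: pd.DataFrame  # screen rows for responsive miRNAs (+family_name)
    removed: pd.DataFrame  # genotype-specific rows with NT evidence
    family_rates: pd.Series  # family -> % of responsive abundance
    main_regulators: list[str]
    directions: pd.DataFrame

    @property
    def responsive_families(self) -> set[str]:
        return set(self.responsive["family_name"]) if len(self.responsive) else set()


def run_stage_analysis(
    counts: CountMatrix,
    design: SampleDesign,
    records: list[MiRNARecord],
    config: StageAnalysisConfig | None = None,
) -> dict[str, StageResponse]:
    """Full pipeline over all four stages.

    normalize -> expression floor -> per-stage DE under HT and NT ->
    genotype-specific removal -> family abundance rates -> main regulators ->
    direction patterns. Deterministic given inputs and config.
    """
    cfg = config or StageAnalysisConfig()
    for stage in STAGES:
        for condition in ("NT", "HT"):
            if not design.libraries(condition=condition, stage=stage):
                raise DesignError(f"stage {stage} has no {condition} libraries")
    expr = apply_expression_floor(normalize_cpm(counts), cfg.tpm_floor)
    abund = expr.tpm.mean(axis=1).to_dict()
    fam_map = family_of(classify(records, abundance=abund))

    out: dict[str, StageResponse] = {}
    for stage in STAGES:
        de = {
            cond: screen(
                expr,
                counts,
                make_contrast(design, stage, cond),
                alpha=cfg.alpha,
                fc_high=cfg.fc_high,
                fc_low=cfg.fc_low,
                pseudocount=cfg.pseudocount,
                adjust=cfg.adjust,
            )
            for cond in ("HT", "NT")
        }
        responsive, removed = remove_genotype_specific(
            de["HT"], de["NT"], mode=cfg.removal_mode
        )
        responsive = responsive.copy()
        responsive["family_name"] = responsive["mirna_id"].map(
            lambda m: fam_map.get(m, m)
        )
        rate_libs = design.libraries(condition=cfg.rate_condition, stage=stage)
        rates = family_abundance_rates(responsive, expr, fam_map, rate_libs)
        out[stage] = StageResponse(
            stage=stage,
            responsive=responsive,
            removed=removed,
            family_rates=rates,
            main_regulators=select_main_regulators(rates, cfg.main_threshold),
            directions=summarize_directions(
                responsive, expr, fam_map, rate_libs, cfg.high_abundance
            ),
        )
    return out


def family_stage_matrix(responses: dict[str, StageResponse]) -> pd.DataFrame:
    """Family x stage membership matrix (1 = family responsive at stage)."""
    fams = sorted({f for r in responses.values() for f in r.responsive_families})
    data = {
        stage: [int(f in r.responsive_families) for f in fams]
        for stage, r in responses.items()
    }
    return pd.DataFrame(data, index=pd.Index(fams, name="family_name"))


def rate_matrix(responses: dict[str, StageResponse]) -> pd.DataFrame:
    """Family x stage abundance-rate matrix (%, 0 where not responsive)."""
    fams = sorted({f for r in responses.values() for f in r.family_rates.index})
    out = pd.DataFrame(0.0, index=pd.Index(fams, name="family_name"), columns=list(responses))
    for stage, r in responses.items():
        for fam, rate in r.family_rates.items():
            out.loc[fam, stage] = rate
    return out
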