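"""Calibration and recovery studies over synthetic data.

These drive the whole pipeline end to end under controlled conditions:

* ``null_calibration`` — unreplicated null datasets (no planted effects,
  Poisson counts) to measure the DE screen's Type-I error. The exact
  conditional test is calibrated for Poisson sampling noise between two
  libraries, which is why the null study runs at nb_dispersion = 0; with
  biological overdispersion an unreplicated design cannot distinguish noise
  from signal, and the measured rate would exceed the nominal level.
* ``recovery_study`` — planted heat-responsive families and planted
  genotype-specific miRNAs, scoring how often the genotype-adjusted
  per-stage screen recovers the former and excludes the latter.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .io import STAGES
from .simulate import PlantedEffect, SimulationConfig, generate_catalog, generate_counts
from .stage_response import StageAnalysisConfig, run_stage_analysis


def study_like_config(seed: int) -> SimulationConfig:
    """A dataset shaped like the target study: 16 unreplicated libraries with
    the seven main-regulator families planted at the stages where they act
    (miR2949/miR167/miR160 at SCP; miR156/miR172 at MP; miR156 at MRP;
    miR393/miR3476 at PM; |log2FC| = 3) plus two genotype-specific decoys."""
    return SimulationConfig(
        n_families=17,
        members_per_family=[2, 2, 2, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1],
        library_size_mean=5e6,
        baseline_log2_tpm_mean=8.0,
        baseline_log2_tpm_sd=1.0,
        nb_dispersion=0.02,
        planted_ht_effects=[
            PlantedEffect("miR2949", "SCP", "down_in_tolerant", 3.0),
            PlantedEffect("miR167", "SCP", "down_in_tolerant", 3.0),
            PlantedEffect("miR160", "SCP", "down_in_tolerant", 3.0),
            PlantedEffect("miR156", "MP", "up_in_tolerant", 3.0),
            PlantedEffect("miR172", "MP", "down_in_tolerant", 3.0),
            PlantedEffect("miR156", "MRP", "up_in_tolerant", 3.0),
            PlantedEffect("miR393", "PM", "up_in_tolerant", 3.0),
            PlantedEffect("miR3476", "PM", "down_in_tolerant", 3.0),
        ],
        planted_nt_genotype_effects=[
            PlantedEffect("miR482", "SCP", "up_in_tolerant", 3.0),
            PlantedEffect("miR535", "MP", "down_in_tolerant", 3.0),
        ],
        rng_seed=seed,
    )


def null_calibration(
    n_mirnas: int = 300,
    n_contrasts: int = 2000,
    library_size: float = 5e6,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Fraction of null miRNAs reaching p <= alpha, and the full-screen call rate.

    Each simulated 16-library dataset contributes its 8 within-stage
    genotype contrasts; datasets are drawn until ``n_contrasts`` have been
    tested. Counts are Poisson (dispersion 0): the regime in which the exact
    conditional test's null distribution is the hypergeometric it assumes.
    """
    from .abundance import normalize_cpm
    from .diffexpr import make_contrast, screen

    rng = np.random.default_rng(seed)
    n_p = 0
    n_called = 0
    n_tests = 0
    contrasts_done = 0
    while contrasts_done < n_contrasts:
        cfg = SimulationConfig(
            n_families=n_mirnas // 2,
            members_per_family=2,
            nb_dispersion=0.0,
            library_size_mean=library_size,
            rng_seed=int(rng.integers(2**31)),
        )
        catalog = generate_catalog(cfg)
        counts, design, _ = generate_counts(catalog, cfg)
        expr = normalize_cpm(counts)  # no floor: keep the test count fixed
        for stage in STAGES:
            for condition in ("HT", "NT"):
                if contrasts_done >= n_contrasts:
                    break
                res = screen(expr, counts, make_contrast(design, stage, condition), alpha=alpha)
                n_p += int((res["p_value"] <= alpha).sum())
                n_called += int((res["call"] != "not_de").sum())
                n_tests += len(res)
                contrasts_done += 1
    return {
        "n_tests": n_tests,
        "n_contrasts": contrasts_done,
        "fraction_p_le_alpha": n_p / n_tests,
        "fraction_screen_called": n_called / n_tests,
    }


def _recovery_config(seed: int) -> SimulationConfig:
    """Planted conditions: |log2FC| = 3 family effects under HT at every
    stage, baseline abundance >= 500 TPM, plus one genotype-specific miRNA
    per stage (a difference present under NT as well)."""
    return SimulationConfig(
        n_families=12,
        members_per_family=2,
        library_size_mean=5e6,
        baseline_log2_tpm_mean=9.0,  # 512 TPM
        baseline_log2_tpm_sd=0.0,
        nb_dispersion=0.05,
        planted_ht_effects=[
            PlantedEffect("miR2949", "SCP", "down_in_tolerant", 3.0),
            PlantedEffect("miR156", "MP", "up_in_tolerant", 3.0),
            PlantedEffect("miR172", "MP", "down_in_tolerant", 3.0),
            PlantedEffect("miR156", "MRP", "up_in_tolerant", 3.0),
            PlantedEffect("miR393", "PM", "up_in_tolerant", 3.0),
        ],
        planted_nt_genotype_effects=[
            PlantedEffect("miR482", "SCP", "up_in_tolerant", 3.0),
            PlantedEffect("miR535", "MP", "down_in_tolerant", 3.0),
            PlantedEffect("miR394", "MRP", "up_in_tolerant", 3.0),
            PlantedEffect("miR396", "PM", "down_in_tolerant", 3.0),
        ],
        rng_seed=seed,
    )


def recovery_study(
    n_runs: int = 200,
    seed: int = 0,
    analysis_config: StageAnalysisConfig | None = None,
) -> dict:
    """Sensitivity/specificity of the genotype-adjusted stage screen.

    Sensitivity: planted (family, stage) heat effects present in the
    responsive family output. Specificity: planted genotype-specific
    (miRNA, stage) pairs absent from the responsive set (they must be
    removed, not reported). Also counts leakage — removed miRNAs appearing
    anywhere in a stage's responsive set or family rates — which must be 0.
    """
    rng = np.random.default_rng(seed)
    planted_found = planted_total = 0
    geno_excluded = geno_total = 0
    leaked = 0
    for _ in range(n_runs):
        cfg = _recovery_config(int(rng.integers(2**31)))
        catalog = generate_catalog(cfg)
        counts, design, truth = generate_counts(catalog, cfg)
        responses = run_stage_analysis(counts, design, catalog, analysis_config)
        for stage in STAGES:
            resp = responses[stage]
            for fam in truth.responsive_families[stage]:
                planted_total += 1
                planted_found += fam in resp.responsive_families
            responsive_ids = set(resp.responsive["mirna_id"])
            for mirna in truth.genotype_specific[stage]:
                geno_total += 1
                geno_excluded += mirna not in responsive_ids
            removed_ids = set(resp.removed["mirna_id"])
            leaked += len(removed_ids & responsive_ids)
            rate_members = set(
                resp.responsive.loc[
                    resp.responsive["family_name"].isin(resp.family_rates.index),
                    "mirna_id",
                ]
            )
            leaked += len(removed_ids & rate_members)
    return {
        "n_runs": n_runs,
        "sensitivity": planted_found / planted_total,
        "specificity": geno_excluded / geno_total,
        "leaked": leaked,
    }
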