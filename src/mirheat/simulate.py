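"""Synthetic small RNA-seq data with planted ground truth.

Emulates the study design the pipeline targets: two cotton lines (tolerant
and sensitive), control and high-temperature conditions, four anther
developmental stages, one library per cell by default (16 libraries), with
negative-binomial count noise around per-miRNA baseline abundances.

Planted heat effects shift the tolerant/sensitive expression ratio of a
whole seed-sharing family under HT only; planted genotype effects shift a
single miRNA under both conditions (a genotype difference, not a heat
response). The ground truth of what was planted is returned alongside the
data so recovery can be scored.

All randomness flows from the single integer ``rng_seed``; each generator
op uses its own derived stream, so outputs are reproducible and independent
of call order.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .families import family_from_name
from .io import (
    CountMatrix,
    MiRNARecord,
    SampleDesign,
    STAGES,
    assign_groups,
    write_mature_fasta,
)

DIRECTIONS = ("up_in_tolerant", "down_in_tolerant")

# Family name pool: the heat-responsive cotton families first, then
# high-numbered tokens for background families.
_FAMILY_POOL = [
    "miR156", "miR160", "miR167", "miR172", "miR393", "miR482", "miR2949",
    "miR3476", "miR535", "miR394", "miR396", "miR827", "miR1530", "miR4344",
    "miR6960", "miR7486", "miR7495",
]


class ConfigurationError(ValueError):
    """A simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class PlantedEffect:
    """One planted log2 expression shift.

    ``target`` is a family name for HT effects or a mirna_id for genotype
    effects; ``direction`` says which way the tolerant line moves.
    """

    target: str
    stage: str
    direction: str
    log2fc: float

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ConfigurationError(f"unknown stage {self.stage!r}")
        if self.direction not in DIRECTIONS:
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        if not np.isfinite(self.log2fc):
            raise ConfigurationError("planted effect sizes must be finite")

    @property
    def signed_log2fc(self) -> float:
        return self.log2fc if self.direction == "up_in_tolerant" else -self.log2fc


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the target design: 16 unreplicated libraries
    (2 genotypes x 2 conditions x 4 stages), ~5e6 mapped reads each,
    baseline abundances lognormal around 2^5 = 32 TPM, mild negative-binomial
    overdispersion, and a read-length profile peaking at 24 nt then 21 nt.
    """

    n_families: int = 20
    members_per_family: int | Sequence[int] = 2
    family_names: Sequence[str] | None = None
    replicates_per_cell: int = 1
    library_size_mean: float = 5e6
    library_size_cv: float = 0.0
    baseline_log2_tpm_mean: float = 5.0
    baseline_log2_tpm_sd: float = 2.0
    nb_dispersion: float = 0.05
    planted_ht_effects: list[PlantedEffect] = field(default_factory=list)
    planted_nt_genotype_effects: list[PlantedEffect] = field(default_factory=list)
    frac_24nt: float = 0.42
    frac_21nt: float = 0.15
    fraction_novel: float = 0.5
    n_decoy_targets: int = 10
    allow_overlap: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ConfigurationError("need at least one family")
        if self.n_families > 4**7:
            raise ConfigurationError("more families than distinct 7-mer seeds")
        if self.replicates_per_cell < 1:
            raise ConfigurationError("replicates_per_cell must be >= 1")
        if self.library_size_mean <= 0:
            raise ConfigurationError("library sizes must be positive")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        for frac in (self.frac_24nt, self.frac_21nt):
            if not 0 < frac < 1:
                raise ConfigurationError("length-profile fractions must be in (0,1)")
        if self.frac_24nt + self.frac_21nt >= 1:
            raise ConfigurationError("length-profile modal fractions must sum to < 1")
        if self.family_names is not None and len(self.family_names) < self.n_families:
            raise ConfigurationError("family_names shorter than n_families")
        if not self.allow_overlap:
            ht = {
                (e.target, e.stage) for e in self.planted_ht_effects
            }  # family-level
            for e in self.planted_nt_genotype_effects:
                fam = family_from_name(e.target)
                if fam is not None and (fam, e.stage) in ht:
                    raise ConfigurationError(
                        f"genotype effect on {e.target} overlaps HT effect on "
                        f"{fam} at {e.stage}; set allow_overlap to permit"
                    )

    def resolved_family_names(self) -> list[str]:
        if self.family_names is not None:
            return list(self.family_names[: self.n_families])
        names = list(_FAMILY_POOL)
        i = 9001
        while len(names) < self.n_families:
            names.append(f"miR{i}")
            i += 1
        return names[: self.n_families]

    def family_sizes(self) -> list[int]:
        if isinstance(self.members_per_family, int):
            return [self.members_per_family] * self.n_families
        sizes = list(self.members_per_family)
        if len(sizes) != self.n_families:
            raise ConfigurationError("members_per_family list must match n_families")
        return sizes


@dataclass
class GroundTruth:
    """What was planted, keyed the way recovery is scored.

    ``responsive_mirnas[stage]`` maps mirna_id -> expected DE direction in
    the tolerant/sensitive HT contrast ('up'/'down');
    ``genotype_specific[stage]`` lists miRNAs whose difference exists under
    NT too and should be removed by the genotype adjustment.
    """

    responsive_mirnas: dict[str, dict[str, str]]
    responsive_families: dict[str, set[str]]
    genotype_specific: dict[str, set[str]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "responsive_mirnas": self.responsive_mirnas,
            "responsive_families": {s: sorted(v) for s, v in self.responsive_families.items()},
            "genotype_specific": {s: sorted(v) for s, v in self.genotype_specific.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed % 2**31, stream])


def _decode_seed(idx: int) -> str:
    out = []
    for _ in range(7):
        out.append("ACGU"[idx % 4])
        idx //= 4
    return "".join(out)


def generate_catalog(config: SimulationConfig) -> list[MiRNARecord]:
    """Generate a mature-miRNA catalog of seed-sharing families.

    Members of a family share nucleotides 2-8 exactly; different families
    get distinct seeds. Names follow the cotton dialect:
    ghr[-novel]-miRNNN[letter][-5p|-3p].
    """
    rng = _rng(config, 1)
    names = config.resolved_family_names()
    sizes = config.family_sizes()
    seed_idx = rng.choice(4**7, size=config.n_families, replace=False)
    seeds = [_decode_seed(int(i)) for i in seed_idx]
    records: list[MiRNARecord] = []
    letters = string.ascii_lowercase
    for fam, size, seed in zip(names, sizes, seeds):
        for j in range(size):
            novel = bool(rng.random() < config.fraction_novel)
            arm = rng.choice(["", "-5p", "-3p"])
            letter = letters[j % 26] * (j // 26 + 1) if size > 1 else ""
            prefix = "ghr-novel-" if novel else "ghr-"
            mirna_id = f"{prefix}{fam}{letter}{arm}"
            length = int(rng.integers(20, 25))
            first = "ACGU"[int(rng.integers(4))]
            tail = "".join("ACGU"[int(b)] for b in rng.integers(0, 4, size=length - 8))
            records.append(
                MiRNARecord(
                    mirna_id=mirna_id,
                    sequence=first + seed + tail,
                    arm=arm.lstrip("-") if arm else "unspecified",
                    status="novel" if novel else "known",
                )
            )
    return assign_groups(records)


def build_design(config: SimulationConfig) -> SampleDesign:
    """The factorial sample sheet with the H/T + C-suffix library dialect.

    H{i}/T{i} = tolerant/sensitive under HT at stage i; HC{i}/TC{i} are the
    NT controls. Replicates, when configured, get a "-r" suffix.
    """
    rows = []
    for s_idx, stage in enumerate(STAGES, start=1):
        for genotype, gcode in (("tolerant", "H"), ("sensitive", "T")):
            for condition, ccode in (("HT", ""), ("NT", "C")):
                for rep in range(1, config.replicates_per_cell + 1):
                    lib = f"{gcode}{ccode}{s_idx}"
                    if config.replicates_per_cell > 1:
                        lib += f"-{rep}"
                    rows.append(
                        {
                            "library_id": lib,
                            "genotype": genotype,
                            "condition": condition,
                            "stage": stage,
                            "replicate": rep,
                        }
                    )
    return SampleDesign(pd.DataFrame(rows))


def _library_sizes(config: SimulationConfig, design: SampleDesign) -> pd.Series:
    rng = _rng(config, 2)
    n = len(design.library_ids)
    if config.library_size_cv == 0:
        sizes = np.full(n, round(config.library_size_mean), dtype=np.int64)
    else:
        sigma = np.sqrt(np.log1p(config.library_size_cv**2))
        mu = np.log(config.library_size_mean) - sigma**2 / 2
        sizes = np.maximum(1, rng.lognormal(mu, sigma, size=n).round()).astype(np.int64)
    return pd.Series(sizes, index=design.library_ids)


def expected_tpm(
    catalog: list[MiRNARecord], config: SimulationConfig, design: SampleDesign
) -> pd.DataFrame:
    """Expected TPM per (miRNA, library): baseline plus planted shifts.

    HT effects multiply the tolerant line's expectation by 2^(+-log2fc)
    under HT at the planted stage; genotype effects do the same under both
    conditions. The sensitive line stays at baseline.
    """
    rng = _rng(config, 3)
    ids = [r.mirna_id for r in catalog]
    base = 2.0 ** rng.normal(
        config.baseline_log2_tpm_mean, config.baseline_log2_tpm_sd, size=len(ids)
    )
    tpm = pd.DataFrame(
        np.tile(base[:, None], (1, len(design.library_ids))),
        index=ids,
        columns=design.library_ids,
    )
    fam_members: dict[str, list[str]] = {}
    for rec in catalog:
        fam = family_from_name(rec.mirna_id)
        if fam is not None:
            fam_members.setdefault(fam, []).append(rec.mirna_id)
    for eff in config.planted_ht_effects:
        members = fam_members.get(eff.target, [])
        if not members:
            raise ConfigurationError(f"planted family {eff.target!r} not in catalog")
        libs = design.libraries(genotype="tolerant", condition="HT", stage=eff.stage)
        tpm.loc[members, libs] *= 2.0**eff.signed_log2fc
    for eff in config.planted_nt_genotype_effects:
        mirna = resolve_mirna(catalog, eff.target)
        libs = design.libraries(genotype="tolerant", stage=eff.stage)
        tpm.loc[mirna, libs] *= 2.0**eff.signed_log2fc
    return tpm


def resolve_mirna(catalog: list[MiRNARecord], target: str) -> str:
    """Resolve a planted-effect target to a concrete mirna_id.

    An exact mirna_id wins; a family token (e.g. "miR160") resolves to the
    family's first member in name order, so effects can be planted without
    knowing the randomized member names.
    """
    ids = {r.mirna_id for r in catalog}
    if target in ids:
        return target
    members = sorted(
        r.mirna_id for r in catalog if family_from_name(r.mirna_id) == target
    )
    if members:
        return members[0]
    raise ConfigurationError(f"planted miRNA {target!r} not in catalog")


def _ground_truth(catalog: list[MiRNARecord], config: SimulationConfig) -> GroundTruth:
    fam_members: dict[str, list[str]] = {}
    for rec in catalog:
        fam = family_from_name(rec.mirna_id)
        if fam is not None:
            fam_members.setdefault(fam, []).append(rec.mirna_id)
    responsive: dict[str, dict[str, str]] = {s: {} for s in STAGES}
    families: dict[str, set[str]] = {s: set() for s in STAGES}
    genotype: dict[str, set[str]] = {s: set() for s in STAGES}
    for eff in config.planted_ht_effects:
        direction = "up" if eff.direction == "up_in_tolerant" else "down"
        for m in fam_members.get(eff.target, []):
            responsive[eff.stage][m] = direction
        families[eff.stage].add(eff.target)
    for eff in config.planted_nt_genotype_effects:
        genotype[eff.stage].add(resolve_mirna(catalog, eff.target))
    return GroundTruth(responsive, families, genotype)


def generate_counts(
    catalog: list[MiRNARecord], config: SimulationConfig
) -> tuple[CountMatrix, SampleDesign, GroundTruth]:
    """Draw the count matrix: NB around expected TPM x library size / 1e6.

    nb_dispersion is the gamma-Poisson dispersion alpha (variance
    mu + alpha*mu^2); alpha = 0 is the Poisson limit used in closed-form
    checks.
    """
    if not catalog:
        raise ConfigurationError("catalog is empty")
    design = build_design(config)
    sizes = _library_sizes(config, design)
    mu = expected_tpm(catalog, config, design) * sizes / 1e6
    rng = _rng(config, 4)
    m = mu.to_numpy()
    if config.nb_dispersion == 0:
        draws = rng.poisson(m)
    else:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, m * config.nb_dispersion)
        draws = rng.poisson(lam)
    counts = pd.DataFrame(
        draws.astype(np.int64), index=mu.index, columns=mu.columns
    )
    sizes = pd.concat([sizes, counts.sum(axis=0)], axis=1).max(axis=1)
    return CountMatrix(counts, sizes), design, _ground_truth(catalog, config)


LENGTH_RANGE = range(16, 31)


def generate_length_profiles(config: SimulationConfig) -> pd.DataFrame:
    """Per-library read-length histograms over 16-30 nt.

    Expected mass frac_24nt at 24 nt and frac_21nt at 21 nt, the remainder
    spread uniformly over the other 13 lengths; drawn multinomially so each
    column sums to its library size.
    """
    design = build_design(config)
    sizes = _library_sizes(config, design)
    lengths = list(LENGTH_RANGE)
    rest = (1.0 - config.frac_24nt - config.frac_21nt) / (len(lengths) - 2)
    probs = np.array(
        [
            config.frac_24nt if l == 24 else config.frac_21nt if l == 21 else rest
            for l in lengths
        ]
    )
    rng = _rng(config, 5)
    data = {
        lib: rng.multinomial(int(sizes[lib]), probs) for lib in design.library_ids
    }
    return pd.DataFrame(data, index=pd.Index(lengths, name="length"))


def generate_target_tables(
    catalog: list[MiRNARecord],
    config: SimulationConfig,
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predicted-target pairs plus a gene-level DE table.

    Every planted responsive miRNA gets one target gene whose DE direction
    at that stage is opposite to the miRNA's (the repression signature);
    decoy pairs point random miRNAs at genes with random directions.
    """
    if not catalog:
        raise ConfigurationError("catalog is empty")
    rng = _rng(config, 6)
    target_rows, gene_rows = [], []
    gene_n = 0
    seen_pairs: set[tuple[str, str]] = set()
    for stage in STAGES:
        for mirna, direction in sorted(truth.responsive_mirnas.get(stage, {}).items()):
            gene_n += 1
            gene = f"Gh_SYN{gene_n:04d}"
            target_rows.append({"mirna_id": mirna, "gene_id": gene})
            seen_pairs.add((mirna, gene))
            gene_rows.append(
                {
                    "gene_id": gene,
                    "stage": stage,
                    "direction": "down" if direction == "up" else "up",
                }
            )
    ids = [r.mirna_id for r in catalog]
    for _ in range(config.n_decoy_targets):
        gene_n += 1
        gene = f"Gh_SYN{gene_n:04d}"
        mirna = ids[int(rng.integers(len(ids)))]
        target_rows.append({"mirna_id": mirna, "gene_id": gene})
        gene_rows.append(
            {
                "gene_id": gene,
                "stage": STAGES[int(rng.integers(len(STAGES)))],
                "direction": ["up", "down"][int(rng.integers(2))],
            }
        )
    return pd.DataFrame(target_rows), pd.DataFrame(gene_rows)


def generate_ct_table(
    config: SimulationConfig,
    truth: GroundTruth,
    n_replicates: int = 3,
    noise_sd: float = 0.15,
) -> pd.DataFrame:
    """Synthetic qPCR Ct values for every planted responsive miRNA.

    One assay per (miRNA, stage); treatment = tolerant line under HT,
    control = sensitive line under HT, so 2^-ddCt estimates the same
    tolerant/sensitive fold change the sequencing contrast measures. The
    planted log2 effect is written into the treatment-vs-control dCt
    difference, plus N(0, noise_sd) per-replicate noise.
    """
    rng = _rng(config, 7)
    effects = {
        (e.target, e.stage): e.signed_log2fc for e in config.planted_ht_effects
    }
    rows = []
    for stage in STAGES:
        for mirna, _direction in sorted(truth.responsive_mirnas.get(stage, {}).items()):
            fam = family_from_name(mirna)
            l2fc = effects.get((fam, stage), 0.0)
            assay = f"{mirna}@{stage}"
            ct_ref = 18.0
            ct_control = 25.0
            for group, shift in (("treatment", -l2fc), ("control", 0.0)):
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{assay}.{group}.{rep}",
                            "target_name": assay,
                            "group": group,
                            "ct_target": ct_control + shift + rng.normal(0, noise_sd),
                            "ct_reference": ct_ref + rng.normal(0, noise_sd),
                        }
                    )
    return pd.DataFrame(rows)


def write_simulation(
    out_dir: str | Path,
    catalog: list[MiRNARecord],
    counts: CountMatrix,
    design: SampleDesign,
    truth: GroundTruth,
    histograms: pd.DataFrame | None = None,
    targets: pd.DataFrame | None = None,
    gene_de: pd.DataFrame | None = None,
    ct_table: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write a simulated dataset as the plain-text files the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["counts"] = out / "counts.tsv"
    counts.counts.rename_axis("mirna_id").to_csv(paths["counts"], sep="\t")
    sheet = design.table.copy()
    sheet["total_reads"] = counts.library_sizes.reindex(sheet["library_id"]).to_numpy()
    paths["sample_sheet"] = out / "sample_sheet.tsv"
    sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
    paths["mature_fasta"] = out / "mature.fa"
    write_mature_fasta(catalog, paths["mature_fasta"])
    paths["ground_truth"] = out / "ground_truth.json"
    truth.to_json(paths["ground_truth"])
    if histograms is not None:
        paths["length_histograms"] = out / "length_histograms.tsv"
        histograms.to_csv(paths["length_histograms"], sep="\t")
    if targets is not None:
        paths["targets"] = out / "targets.tsv"
        targets.to_csv(paths["targets"], sep="\t", index=False)
    if gene_de is not None:
        paths["gene_de"] = out / "gene_de.tsv"
        gene_de.to_csv(paths["gene_de"], sep="\t", index=False)
    if ct_table is not None:
        paths["ct_table"] = out / "ct_values.tsv"
        ct_table.to_csv(paths["ct_table"], sep="\t", index=False)
    return paths
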