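"""Readers and writers for the tabular and sequence formats the pipeline touches.

Counts, sample sheets, length histograms, target tables and Ct tables are all
plain TSV with one header row; mature miRNA sequences are FASTA with
miRBase-style headers. Every reader validates fully before returning: a
malformed file never yields a partially populated object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

GENOTYPES = ("tolerant", "sensitive")
CONDITIONS = ("NT", "HT")
STAGES = ("SCP", "MP", "MRP", "PM")

_RNA_ALPHABET = frozenset("ACGU")


class ParseError(ValueError):
    """A file failed validation while being read."""


class DesignError(ValueError):
    """Sample metadata is inconsistent with the data it describes."""


@dataclass(frozen=True)
class MiRNARecord:
    """One mature miRNA.

    ``group_id`` ties together miRNAs with byte-identical mature sequences
    (reported joined with " > " in result tables); it is the identifier of the
    first group member encountered.
    """

    mirna_id: str
    sequence: str
    arm: str = "unspecified"  # {5p, 3p, unspecified}
    status: str = "known"  # {known, novel}
    group_id: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise ParseError(
                f"{self.mirna_id}: non-RNA characters {sorted(bad)} in sequence"
            )
        if self.arm not in ("5p", "3p", "unspecified"):
            raise ValueError(f"{self.mirna_id}: bad arm {self.arm!r}")
        if self.status not in ("known", "novel"):
            raise ValueError(f"{self.mirna_id}: bad status {self.status!r}")
        if not self.group_id:
            object.__setattr__(self, "group_id", self.mirna_id)


def _parse_arm(mirna_id: str) -> str:
    if mirna_id.endswith("-5p"):
        return "5p"
    if mirna_id.endswith("-3p"):
        return "3p"
    return "unspecified"


def make_record(mirna_id: str, sequence: str, group_id: str = "") -> MiRNARecord:
    """Build a record, normalizing DNA bases to RNA and parsing the name dialect.

    The "-novel" infix marks predicted (non-miRBase) miRNAs; a trailing
    -5p/-3p names the precursor arm.
    """
    seq = sequence.strip().upper().replace("T", "U")
    status = "novel" if "-novel" in mirna_id else "known"
    return MiRNARecord(
        mirna_id=mirna_id,
        sequence=seq,
        arm=_parse_arm(mirna_id),
        status=status,
        group_id=group_id,
    )


def assign_groups(records: list[MiRNARecord]) -> list[MiRNARecord]:
    """Assign a shared group_id to records with identical sequences.

    The group id is the mirna_id of the first member encountered, so the
    result is deterministic for a fixed input order.
    """
    first_seen: dict[str, str] = {}
    out = []
    for rec in records:
        gid = first_seen.setdefault(rec.sequence, rec.mirna_id)
        out.append(
            MiRNARecord(rec.mirna_id, rec.sequence, rec.arm, rec.status, gid)
        )
    return out


def read_mature_fasta(path: str | Path) -> list[MiRNARecord]:
    """Read mature miRNA sequences from FASTA.

    T is normalized to U; arm and known/novel status are parsed from the
    header; records sharing a sequence share a group_id.
    """
    records = []
    seen_ids: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen_ids:
            raise ParseError(f"{path}: duplicate miRNA id {entry.id!r}")
        seen_ids.add(entry.id)
        records.append(make_record(entry.id, str(entry.seq)))
    return assign_groups(records)


def write_mature_fasta(records: list[MiRNARecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.mirna_id}\n{rec.sequence}\n")


@dataclass
class SampleDesign:
    """Factorial metadata: one row per library.

    Columns: library_id, genotype, condition, stage, replicate.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["library_id", "genotype", "condition", "stage", "replicate"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise DesignError(f"sample sheet missing columns: {missing}")
        t = self.table
        if t["library_id"].duplicated().any():
            dups = t.loc[t["library_id"].duplicated(), "library_id"].tolist()
            raise DesignError(f"duplicate library ids: {dups}")
        for col, allowed in (
            ("genotype", GENOTYPES),
            ("condition", CONDITIONS),
            ("stage", STAGES),
        ):
            bad = set(t[col]) - set(allowed)
            if bad:
                raise DesignError(f"unknown {col} values: {sorted(bad)}")
        if (t["replicate"].astype(int) < 1).any():
            raise DesignError("replicate indices must be >= 1")
        cells = t[["genotype", "condition", "stage", "replicate"]]
        if cells.duplicated().any():
            raise DesignError("duplicate (genotype, condition, stage, replicate) cells")

    @property
    def library_ids(self) -> list[str]:
        return self.table["library_id"].tolist()

    def libraries(
        self,
        genotype: str | None = None,
        condition: str | None = None,
        stage: str | None = None,
    ) -> list[str]:
        t = self.table
        mask = pd.Series(True, index=t.index)
        if genotype is not None:
            mask &= t["genotype"] == genotype
        if condition is not None:
            mask &= t["condition"] == condition
        if stage is not None:
            mask &= t["stage"] == stage
        return t.loc[mask, "library_id"].tolist()

    def is_full_factorial(self) -> bool:
        cells = {
            (g, c, s)
            for g, c, s in self.table[["genotype", "condition", "stage"]].itertuples(
                index=False
            )
        }
        return all(
            (g, c, s) in cells for g in GENOTYPES for c in CONDITIONS for s in STAGES
        )


@dataclass
class CountMatrix:
    """Raw counts over miRNAs x libraries plus per-library total mapped reads.

    ``library_sizes`` are the normalization denominators; they may exceed the
    column sums because library totals include non-miRNA reads.
    """

    counts: pd.DataFrame  # index = mirna ids, columns = library ids, int
    library_sizes: pd.Series  # index = library ids

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            raise ParseError(f"duplicate miRNA ids: {c.index[c.index.duplicated()].tolist()}")
        if c.columns.duplicated().any():
            raise ParseError("duplicate library ids in count matrix")
        if not np.issubdtype(c.to_numpy().dtype, np.integer):
            raise ParseError("count matrix cells must be integers")
        if (c.to_numpy() < 0).any():
            bad = c.stack()
            bad = bad[bad < 0].index[0]
            raise ParseError(f"negative count at miRNA {bad[0]!r}, library {bad[1]!r}")
        self.library_sizes = self.library_sizes.reindex(c.columns)
        if self.library_sizes.isna().any():
            missing = self.library_sizes.index[self.library_sizes.isna()].tolist()
            raise DesignError(f"libraries without a total-read count: {missing}")
        colsums = c.sum(axis=0)
        short = self.library_sizes < colsums
        if short.any():
            raise DesignError(
                "library sizes smaller than miRNA column sums for: "
                f"{self.library_sizes.index[short].tolist()}"
            )

    @property
    def mirna_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def library_ids(self) -> list[str]:
        return self.counts.columns.tolist()


def read_sample_sheet(path: str | Path) -> SampleDesign:
    table = pd.read_csv(path, sep="\t", dtype={"library_id": str})
    return SampleDesign(table)


def read_counts(
    path: str | Path, sample_sheet_path: str | Path
) -> tuple[CountMatrix, SampleDesign]:
    """Read a miRNA x library count TSV together with its sample sheet.

    Library sizes come from a ``total_reads`` sample-sheet column when
    present, otherwise they default to the count column sums.
    """
    design = read_sample_sheet(sample_sheet_path)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    for col in raw.columns:
        vals = raw[col]
        if not np.issubdtype(vals.dtype, np.number) or (vals % 1 != 0).any():
            bad_row = vals.index[~vals.apply(lambda v: float(v).is_integer())][0]
            raise ParseError(
                f"{path}: non-integer count at miRNA {bad_row!r}, library {col!r}"
            )
    counts = raw.astype(np.int64)
    unknown = set(counts.columns) - set(design.library_ids)
    if unknown:
        raise DesignError(
            f"libraries in counts absent from sample sheet: {sorted(unknown)}"
        )
    missing = set(design.library_ids) - set(counts.columns)
    if missing:
        raise DesignError(f"sample-sheet libraries missing from counts: {sorted(missing)}")
    counts = counts[design.library_ids]
    if "total_reads" in design.table.columns:
        sizes = pd.Series(
            design.table["total_reads"].to_numpy(dtype=np.int64),
            index=design.table["library_id"].to_numpy(),
        )
    else:
        sizes = counts.sum(axis=0)
    return CountMatrix(counts, sizes), design


def read_length_histograms(path: str | Path) -> pd.DataFrame:
    """Read a read-length histogram TSV: rows = length (nt), columns = libraries."""
    hist = pd.read_csv(path, sep="\t", index_col=0)
    hist.index = hist.index.astype(int)
    if (hist.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative histogram count")
    return hist


def read_target_table(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("mirna_id", "gene_id"):
        if col not in t.columns:
            raise ParseError(f"{path}: target table missing column {col!r}")
    return t


def read_gene_de_table(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "stage", "direction"):
        if col not in t.columns:
            raise ParseError(f"{path}: gene DE table missing column {col!r}")
    bad = set(t["direction"]) - {"up", "down"}
    if bad:
        raise ParseError(f"{path}: unknown gene DE directions {sorted(bad)}")
    return t


def read_ct_table(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    required = ("sample_id", "target_name", "group", "ct_target", "ct_reference")
    for col in required:
        if col not in t.columns:
            raise ParseError(f"{path}: Ct table missing column {col!r}")
    for col in ("ct_target", "ct_reference"):
        vals = t[col]
        if vals.isna().any():
            bad = t.loc[vals.isna(), "sample_id"].tolist()
            raise ParseError(f"{path}: missing {col} for samples {bad}")
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ParseError(f"{path}: {col} values must be finite and positive")
    return t


_SORT_PRECEDENCE = ["stage", "family_name", "mirna_id"]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    summary: dict | None = None,
) -> dict[str, Path]:
    """Write result tables as TSV plus a machine-readable JSON summary.

    Rows are sorted by stage, then family, then miRNA id (whichever of those
    columns exist) so repeated runs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in tables.items():
        path = out / f"{name}.tsv"
        table = table.reset_index(drop=True)  # only columns are written
        sort_cols = [c for c in _SORT_PRECEDENCE if c in table.columns]
        if sort_cols:
            table = table.sort_values(sort_cols, kind="mergesort")
        try:
            table.to_csv(path, sep="\t", index=False)
        except OSError as exc:  # pragma: no cover - environment dependent
            raise OSError(f"failed writing {path}: {exc}") from exc
        written[name] = path
    summary_path = out / "run_summary.json"
    payload = {"tables": sorted(tables)}
    if summary:
        payload.update(summary)
    summary_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    written["run_summary"] = summary_path
    return written


def joined_name(records: list[MiRNARecord], abundance: Mapping[str, float] | None = None) -> str:
    """Render a group of identical-sequence miRNAs as a " > "-joined name.

    Members are ordered by descending mean abundance when provided, otherwise
    alphabetically. Ordering inside joined names is a reporting convention,
    recorded in the run summary.
    """
    ids = [r.mirna_id for r in records]
    if abundance is not None:
        ids.sort(key=lambda m: (-float(abundance.get(m, 0.0)), m))
    else:
        ids.sort()
    return " > ".join(ids)
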