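"""miRNA family classification by name token and by seed sequence.

The seed — nucleotides 2-8 from the mature 5' end — defines family membership
for entries without a parseable miR name token; a name token (e.g. "miR156"
in "ghr-novel-miR156e-3p") always takes precedence, because known and novel
members of the same numbered family are grouped together regardless of seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .io import MiRNARecord

_MIR_TOKEN = re.compile(r"(?:^|-)(mir)(\d+)", re.IGNORECASE)


def extract_seed(sequence: str) -> str:
    """Return the seed: characters at 1-based positions 2-8 of the sequence."""
    if len(sequence) < 8:
        raise ValueError(
            f"sequence of length {len(sequence)} has no complete 2-8 nt seed"
        )
    return sequence[1:8]


def family_from_name(mirna_id: str) -> str | None:
    """Extract the canonical family token ("miR" + number) from a miRNA name.

    Species prefix, "-novel-" infix, member letter and arm suffix are all
    ignored; names without a miR token yield None.
    """
    m = _MIR_TOKEN.search(mirna_id)
    if m is None:
        return None
    return "miR" + m.group(2)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class Family:
    """A miRNA family: member ids, the seeds they carry, and bookkeeping flags."""

    family_name: str
    members: list[str]
    seeds: set[str] = field(default_factory=set)
    named: bool = True

    @property
    def multimember(self) -> bool:
        return len(self.members) >= 2


def classify(
    records: list[MiRNARecord],
    seed_mismatches: int = 0,
    abundance: Mapping[str, float] | None = None,
) -> list[Family]:
    """Partition a catalog into families.

    Records with a parseable miR name token are grouped by that token.
    Unnamed records are clustered by seed, single-linkage at up to
    ``seed_mismatches`` differences (0 = exact seed identity), into
    species-specific families named "fam-novel-NNN". Identical-sequence
    groups (shared group_id) are never split; a group spanning two name
    tokens is a validation error.
    """
    if not records:
        raise ValueError("cannot classify an empty catalog")
    if seed_mismatches not in (0, 1):
        raise ValueError("seed_mismatches must be 0 or 1")

    by_group: dict[str, set[str | None]] = {}
    for rec in records:
        by_group.setdefault(rec.group_id, set()).add(family_from_name(rec.mirna_id))
    conflicts = {
        gid: sorted(str(t) for t in tokens)
        for gid, tokens in by_group.items()
        if len({t for t in tokens if t is not None}) > 1
    }
    if conflicts:
        raise ValueError(
            f"identical-sequence groups span multiple family tokens: {conflicts}"
        )

    named: dict[str, Family] = {}
    unnamed: list[MiRNARecord] = []
    for rec in records:
        token = family_from_name(rec.mirna_id)
        if token is None:
            unnamed.append(rec)
            continue
        fam = named.setdefault(token, Family(token, [], set(), named=True))
        fam.members.append(rec.mirna_id)
        fam.seeds.add(extract_seed(rec.sequence))

    clusters = _cluster_by_seed(unnamed, seed_mismatches)
    # Deterministic numbering: by descending total abundance when given,
    # else by first member id.
    def cluster_key(cl: list[MiRNARecord]):
        if abundance is not None:
            total = sum(float(abundance.get(r.mirna_id, 0.0)) for r in cl)
            return (-total, min(r.mirna_id for r in cl))
        return (min(r.mirna_id for r in cl),)

    seed_families = []
    for i, cl in enumerate(sorted(clusters, key=cluster_key), start=1):
        seed_families.append(
            Family(
                family_name=f"fam-novel-{i:03d}",
                members=[r.mirna_id for r in cl],
                seeds={extract_seed(r.sequence) for r in cl},
                named=False,
            )
        )
    return [named[k] for k in sorted(named)] + seed_families


def _cluster_by_seed(
    records: list[MiRNARecord], mismatches: int
) -> list[list[MiRNARecord]]:
    """Single-linkage clustering of records whose seeds differ at <= mismatches."""
    n = len(records)
    seeds = [extract_seed(r.sequence) for r in records]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _hamming(seeds[i], seeds[j]) <= mismatches:
                parent[find(i)] = find(j)
    groups: dict[int, list[MiRNARecord]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(find(i), []).append(rec)
    return list(groups.values())


def family_of(families: list[Family]) -> dict[str, str]:
    """Map each member mirna_id to its family name."""
    out: dict[str, str] = {}
    for fam in families:
        for m in fam.members:
            out[m] = fam.family_name
    return out


def family_size_table(families: list[Family]) -> pd.DataFrame:
    """Member-count table, largest families first.

    The returned frame carries ``attrs['n_multimember']`` and
    ``attrs['n_single']`` summary counts.
    """
    rows = [
        {
            "family_name": f.family_name,
            "n_members": len(f.members),
            "multimember": f.multimember,
        }
        for f in families
    ]
    table = pd.DataFrame(rows, columns=["family_name", "n_members", "multimember"])
    if len(table):
        table = table.sort_values(
            ["n_members", "family_name"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    table.attrs["n_multimember"] = int(table["multimember"].sum()) if len(table) else 0
    table.attrs["n_single"] = int((~table["multimember"]).sum()) if len(table) else 0
    return table
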