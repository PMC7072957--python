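"""Library-size normalization, expression floor, abundance bands, read-length stats.

Normalized abundance is counts-per-million of total mapped reads
(count / total_reads * 1e6). Following the source data's convention the
column is labelled "TPM" throughout, but the quantity is CPM: no transcript
length enters the formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix


@dataclass
class ExpressionMatrix:
    """Normalized abundances (CPM, labelled TPM) over miRNAs x libraries."""

    tpm: pd.DataFrame

    @property
    def mirna_ids(self) -> list[str]:
        return self.tpm.index.tolist()

    @property
    def library_ids(self) -> list[str]:
        return self.tpm.columns.tolist()


def normalize_cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Scale each library to reads-per-million of its total mapped reads."""
    sizes = counts.library_sizes
    zero = sizes[sizes <= 0]
    if len(zero):
        raise ValueError(f"zero-size libraries cannot be normalized: {zero.index.tolist()}")
    tpm = counts.counts / sizes.astype(float) * 1e6
    return ExpressionMatrix(tpm)


def apply_expression_floor(expr: ExpressionMatrix, floor: float = 10.0) -> ExpressionMatrix:
    """Drop miRNAs whose abundance is below ``floor`` in every library.

    A miRNA survives if TPM >= floor in at least one library (a miRNA at
    exactly the floor is kept); survivor order is preserved.
    """
    if floor < 0:
        raise ValueError("floor must be nonnegative")
    keep = (expr.tpm >= floor).any(axis=1)
    return ExpressionMatrix(expr.tpm.loc[keep])


def classify_abundance(
    expr: ExpressionMatrix,
    libraries: list[str] | None = None,
    high: float = 500.0,
    low_band_upper: float | None = None,
    stat: str = "max",
) -> pd.Series:
    """Assign each miRNA an abundance band from its TPM over ``libraries``.

    Two-band mode (default): high when the summary TPM >= ``high``, else low.
    Passing ``low_band_upper`` turns on three bands, splitting {low, moderate}
    at that threshold. The summary statistic is the max TPM across the
    libraries (configurable to the mean).
    """
    if high < 0 or (low_band_upper is not None and low_band_upper < 0):
        raise ValueError("abundance thresholds must be nonnegative")
    if low_band_upper is not None and not high > low_band_upper:
        raise ValueError("high threshold must exceed the moderate/low split")
    sub = expr.tpm if libraries is None else expr.tpm[libraries]
    if stat == "max":
        summary = sub.max(axis=1)
    elif stat == "mean":
        summary = sub.mean(axis=1)
    else:
        raise ValueError(f"unknown summary stat {stat!r}")
    band = pd.Series("low", index=sub.index, name="band")
    if low_band_upper is not None:
        band[summary >= low_band_upper] = "moderate"
    band[summary >= high] = "high"
    return band


@dataclass
class LengthProfile:
    """Per-library read-length summary over 16-30 nt.

    ratio_24_21 is the 24 nt / 21 nt read-count ratio, a proxy for
    siRNA-driven DNA-methylation activity; None when the 21 nt bin is empty.
    follows_24_21 flags whether 24 nt is the modal length with 21 nt second.
    """

    library_id: str
    counts: pd.Series
    modal_length: int
    second_length: int
    ratio_24_21: float | None
    follows_24_21: bool


def length_statistics(histograms: pd.DataFrame) -> list[LengthProfile]:
    """Summarize per-library read-length histograms (rows=length, cols=library)."""
    if 21 not in histograms.index or 24 not in histograms.index:
        raise ValueError("length histograms must cover 21 and 24 nt")
    profiles = []
    for lib in histograms.columns:
        counts = histograms[lib]
        order = counts.sort_values(ascending=False, kind="mergesort")
        modal, second = int(order.index[0]), int(order.index[1])
        c21, c24 = float(counts.loc[21]), float(counts.loc[24])
        ratio = c24 / c21 if c21 > 0 else None
        profiles.append(
            LengthProfile(
                library_id=str(lib),
                counts=counts,
                modal_length=modal,
                second_length=second,
                ratio_24_21=ratio,
                follows_24_21=(modal == 24 and second == 21),
            )
        )
    return profiles


def length_profile_frame(profiles: list[LengthProfile]) -> pd.DataFrame:
    rows = [
        {
            "library_id": p.library_id,
            "modal_length": p.modal_length,
            "second_length": p.second_length,
            "ratio_24_21": np.nan if p.ratio_24_21 is None else p.ratio_24_21,
            "follows_24_21": p.follows_24_21,
        }
        for p in profiles
    ]
    return pd.DataFrame(rows)
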