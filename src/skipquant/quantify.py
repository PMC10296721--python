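"""Per-sample skipped-isoform percentages and the de-identified cohort table.

The per-sample statistic is the junction-read share of the skip isoform,

    pct_skipped = 100 * n_delta2 / (n_alpha + n_delta2),

i.e. a percent-spliced-out over the junction evidence only: reads that never
cross the diagnostic window (shared exons) do not enter the denominator, and
no length normalization is needed because both junction windows have the same
width by construction.  A sample with zero junction reads has an undefined
ratio, reported explicitly as NA — never silently 0.

Cohort tables are de-identified before release: original sample identifiers
are replaced by unlinked sequential numbers assigned in a seeded random
order, and any nucleotide-sequence column is masked with an equal-length run
of N.  The mapping back to original IDs is written only to a separate,
optional file.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import SampleCounts

__all__ = [
    "SampleQuant",
    "CohortTable",
    "compute_ratio",
    "flag_splicing",
    "build_cohort_table",
    "deidentify",
    "write_summary",
    "read_summary",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = [
    "sample_id",
    "group",
    "sex",
    "apoe",
    "n_alpha",
    "n_delta2",
    "n_junction_reads",
    "pct_skipped",
    "has_splicing",
]


@dataclass(frozen=True)
class SampleQuant:
    """One sample's skipped-isoform quantification plus metadata passthrough."""

    sample_id: str
    n_alpha: int
    n_delta2: int
    pct_skipped: Optional[float]  # None == NA (no junction reads)
    has_splicing: bool
    group: str = ""
    sex: str = ""
    apoe: str = ""

    @property
    def n_junction_reads(self) -> int:
        return self.n_alpha + self.n_delta2


@dataclass
class CohortTable:
    """Ordered per-sample rows plus a provenance block.

    ``data`` carries at least :data:`SUMMARY_COLUMNS`; ``provenance`` is a
    mapping serialized as leading ``#`` comment lines of the summary TSV
    (pipeline version, parameters, seed).
    """

    data: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.data["sample_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate sample IDs: {dupes}")


def flag_splicing(n_delta2: int, min_skip_reads: int = 1) -> bool:
    """A sample contains skipped transcripts iff enough skip-junction reads."""
    return n_delta2 >= min_skip_reads


def compute_ratio(counts: SampleCounts, min_skip_reads: int = 1, **metadata: str) -> SampleQuant:
    """Junction-read share of the skipped isoform, as a percentage.

    NA (no junction reads at all) is preserved as ``None`` and rendered
    ``NA`` at I/O; such samples still count as splicing-negative for
    prevalence.
    """
    denom = counts.n_alpha + counts.n_delta2
    pct = 100.0 * counts.n_delta2 / denom if denom > 0 else None
    return SampleQuant(
        sample_id=counts.sample_id,
        n_alpha=counts.n_alpha,
        n_delta2=counts.n_delta2,
        pct_skipped=pct,
        has_splicing=flag_splicing(counts.n_delta2, min_skip_reads),
        **metadata,
    )


def build_cohort_table(
    quants: Sequence[SampleQuant], provenance: Optional[dict[str, str]] = None
) -> CohortTable:
    rows = [
        {
            "sample_id": q.sample_id,
            "group": q.group,
            "sex": q.sex,
            "apoe": q.apoe,
            "n_alpha": q.n_alpha,
            "n_delta2": q.n_delta2,
            "n_junction_reads": q.n_junction_reads,
            "pct_skipped": math.nan if q.pct_skipped is None else q.pct_skipped,
            "has_splicing": bool(q.has_splicing),
        }
        for q in quants
    ]
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return CohortTable(data=df, provenance=dict(provenance or {}))


def deidentify(
    table: CohortTable,
    seed: int = 0,
    *,
    id_map_out: Optional[str | Path] = None,
    sequence_columns: Sequence[str] = (),
) -> CohortTable:
    """Replace sample IDs with unlinked numbers; mask sequence columns with N.

    New IDs are the integers ``1..n`` assigned in a seeded random order, so
    the released table's row identity cannot be linked back to input order or
    original labels.  The original→new mapping is written only if
    ``id_map_out`` is given.
    """
    df = table.data.copy()
    original = df["sample_id"].astype(str).tolist()
    if len(set(original)) != len(original):
        raise ValueError("duplicate original sample IDs")
    rng = np.random.default_rng(seed)
    new_ids = rng.permutation(np.arange(1, len(original) + 1))
    mapping = {orig: int(new) for orig, new in zip(original, new_ids)}
    df["sample_id"] = [mapping[o] for o in original]
    for col in sequence_columns:
        if col in df.columns:
            df[col] = df[col].astype(str).map(lambda s: "N" * len(s))
    if id_map_out is not None:
        with open(id_map_out, "w", newline="\n") as fh:
            fh.write("original_id\tdeidentified_id\n")
            for orig in original:
                fh.write(f"{orig}\t{mapping[orig]}\n")
    provenance = dict(table.provenance)
    provenance["deidentified"] = "true"
    return CohortTable(data=df, provenance=provenance)


def _format_value(col: str, v: object) -> str:
    if col == "pct_skipped":
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return "NA"
        return f"{float(v):.4f}"
    if col == "has_splicing":
        return "true" if bool(v) else "false"
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    return str(v)


def write_summary(table: CohortTable, path: str | Path) -> None:
    """Serialize the cohort table as a de-identified tab-delimited file.

    Deterministic column order, NA rendered literally, fixed 4-decimal
    percentages, provenance as leading ``#`` comments, Unix newlines.
    """
    cols = [c for c in SUMMARY_COLUMNS if c in table.data.columns]
    extra = [c for c in table.data.columns if c not in cols]
    cols = cols + extra
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for k, v in table.provenance.items():
                fh.write(f"# {k}={v}\n")
            fh.write("\t".join(cols) + "\n")
            for _, row in table.data.iterrows():
                fh.write("\t".join(_format_value(c, row[c]) for c in cols) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write summary to {path}: {exc}") from exc


def read_summary(path: str | Path) -> CohortTable:
    """Read back a summary TSV written by :func:`write_summary`."""
    provenance: dict[str, str] = {}
    body = io.StringIO()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                provenance[key.strip()] = value.strip()
            else:
                body.write(line)
    body.seek(0)
    df = pd.read_csv(
        body,
        sep="\t",
        na_values=["NA"],
        keep_default_na=False,
        dtype={"sample_id": str, "group": str, "sex": str, "apoe": str},
    )
    if "has_splicing" in df.columns and df["has_splicing"].dtype == object:
        df["has_splicing"] = df["has_splicing"].map({"true": True, "false": False})
    return CohortTable(data=df, provenance=provenance)
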