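"""End-to-end orchestration: classify → quantify → link metadata → de-identify → stats.

A run consumes a manifest (sample_id, reads_path, plus metadata columns),
classifies every sample's reads against the isoform pair, joins the
quantification to the metadata the way the source cohort links RNA-seq
datasets to clinical records, de-identifies the result, and writes the
summary table and statistics report with full provenance.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .classify import ClassifierParams, classify_sample
from .quantify import (
    CohortTable,
    build_cohort_table,
    compute_ratio,
    deidentify,
    write_summary,
)
from .references import IsoformPair
from .stats import cohort_report, write_stats_report

__all__ = ["RunConfig", "run_pipeline", "link_metadata", "read_manifest"]

log = logging.getLogger("skipquant")

MANIFEST_COLUMNS = ["sample_id", "reads_path"]
METADATA_KEY = "sample_id"


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs beyond the manifest itself."""

    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    min_skip_reads: int = 1
    seed: int = 0
    out_dir: str = "skipquant_out"
    group_col: str = "group"
    case_group: str = "AD"
    control_group: str = "NCI"
    keep_going: bool = False
    write_calls: bool = False
    min_group_size: int = 3

    def provenance(self, pair: IsoformPair) -> dict[str, str]:
        c = self.classifier
        w = pair.window_1based
        return {
            "pipeline": f"skipquant {__version__}",
            "canonical": pair.canonical.transcript_id,
            "skipped": pair.skipped.transcript_id,
            "skipped_exon": pair.canonical.labels[pair.skipped_exon_index - 1],
            "window_1based": f"{w[0]}-{w[1]}" if w else "unset",
            "min_anchor": str(c.min_anchor),
            "max_mismatch_in_window": str(c.max_mismatch_in_window),
            "overlap_mode": c.overlap_mode,
            "scoring": f"match={c.match_score:g},mismatch={c.mismatch_penalty:g},"
            f"gap_open={c.gap_open:g},gap_extend={c.gap_extend:g}",
            "min_skip_reads": str(self.min_skip_reads),
            "na_policy": "NA ratios excluded from rank tests, kept in prevalence",
            "seed": str(self.seed),
        }


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required columns {missing}")
    base = Path(path).parent
    df["reads_path"] = [
        str(p) if Path(p).is_absolute() else str(base / p) for p in df["reads_path"]
    ]
    return df


def link_metadata(
    quant_rows: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Inner-join quantification to metadata on sample_id.

    Returns (joined, unmatched_quant, unmatched_metadata); unmatched rows on
    either side are reported, never silently dropped without trace.
    """
    if METADATA_KEY not in metadata.columns:
        raise ValueError(f"metadata lacks key column {METADATA_KEY!r}")
    meta = metadata.drop_duplicates(subset=METADATA_KEY)
    overlap = [
        c for c in meta.columns if c != METADATA_KEY and c in quant_rows.columns
    ]
    joined = quant_rows.drop(columns=overlap).merge(meta, on=METADATA_KEY, how="inner")
    unmatched_q = quant_rows[~quant_rows[METADATA_KEY].isin(meta[METADATA_KEY])]
    unmatched_m = meta[~meta[METADATA_KEY].isin(quant_rows[METADATA_KEY])]
    return joined, unmatched_q, unmatched_m


def run_pipeline(
    pair: IsoformPair,
    manifest: pd.DataFrame,
    config: Optional[RunConfig] = None,
    *,
    metadata: Optional[pd.DataFrame] = None,
) -> tuple[CohortTable, pd.DataFrame]:
    """Run the full per-sample quantification and cohort statistics.

    ``manifest`` must contain sample_id and reads_path (FASTQ or SAM/BAM) and
    may carry the metadata columns directly; a separate ``metadata`` table is
    joined on sample_id when given.  Returns the de-identified cohort table
    and the statistics report; both are also written under ``config.out_dir``
    together with per-sample counts and the ID map.
    """
    config = config or RunConfig()
    ids = manifest["sample_id"].astype(str)
    if ids.duplicated().any():
        raise ValueError(
            f"duplicate sample_id in manifest: {sorted(ids[ids.duplicated()].unique())}"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if metadata is not None:
        manifest, unmatched_q, unmatched_m = link_metadata(manifest, metadata)
        if len(unmatched_q) or len(unmatched_m):
            msg = (
                f"unmatched manifest IDs: {unmatched_q['sample_id'].tolist()}; "
                f"unmatched metadata IDs: {unmatched_m['sample_id'].tolist()}"
            )
            if not config.keep_going:
                raise ValueError(msg)
            log.warning(msg)

    quants = []
    counts_rows = []
    for _, row in manifest.iterrows():
        sid = str(row["sample_id"])
        calls_out = out / f"{sid}.calls.tsv" if config.write_calls else None
        try:
            counts, _ = classify_sample(
                row["reads_path"], pair, config.classifier,
                sample_id=sid, calls_out=calls_out,
            )
        except Exception:
            if config.keep_going:
                log.exception("sample %s failed; continuing", sid)
                continue
            raise
        quants.append(
            compute_ratio(
                counts,
                config.min_skip_reads,
                group=str(row.get(config.group_col, "")),
                sex=str(row.get("sex", "")),
                apoe=str(row.get("apoe", "")),
            )
        )
        counts_rows.append(
            {
                "sample_id": sid,
                "n_alpha": counts.n_alpha,
                "n_delta2": counts.n_delta2,
                "n_ambiguous": counts.n_ambiguous,
                "n_nonjunction": counts.n_nonjunction,
                "n_total": counts.n_total,
            }
        )
    pd.DataFrame(counts_rows).to_csv(out / "counts.tsv", sep="\t", index=False)
    table = build_cohort_table(quants, provenance=config.provenance(pair))
    table = deidentify(table, seed=config.seed, id_map_out=out / "id_map.tsv")
    write_summary(table, out / "summary.tsv")

    group_sizes = table.data[table.data["group"] != ""]["group"].value_counts()
    enough = (
        {config.case_group, config.control_group} <= set(group_sizes.index)
        and group_sizes.get(config.case_group, 0) >= config.min_group_size
        and group_sizes.get(config.control_group, 0) >= config.min_group_size
    )
    if enough:
        report = cohort_report(
            table.data,
            group_col="group",
            case_group=config.case_group,
            control_group=config.control_group,
        )
    else:
        report = pd.DataFrame(
            [
                {
                    "contrast": f"{config.case_group}_vs_{config.control_group}",
                    "statistic_name": "mann_whitney_U",
                    "group_sizes": "/".join(
                        str(group_sizes.get(g, 0))
                        for g in (config.case_group, config.control_group)
                    ),
                    "statistic": float("nan"),
                    "p_value": float("nan"),
                    "sidedness": "two_sided",
                    "note": f"skipped: fewer than {config.min_group_size} samples per group",
                    "p_bonferroni": float("nan"),
                }
            ]
        )
        log.warning("statistics skipped: %s", report.iloc[0]["note"])
    write_stats_report(report, out / "stats.tsv", out / "stats.txt")
    return table, report


def _configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
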