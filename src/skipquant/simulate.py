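"""Synthetic two-isoform RNA-seq reads and mock case-control cohorts.

Every downstream stage of the pipeline (classification, quantification,
statistics) was designed against controlled-access cohort RNA-seq that cannot
ship with the package.  This module stands in for those data: it draws short
reads from a mixture of the canonical and exon-skipped transcripts with a
known skipping fraction, and whole mock cohorts in which each sample's true
fraction comes from a group-dependent zero-inflated Beta distribution and the
metadata table carries diagnosis/sex/APOE/age columns with frequencies
matching the published AD/NCI cohort structure.

The generative model is deliberately minimal so that truth tables are exact
oracles: uniform fragment start (no positional bias), substitution-only
errors, constant base quality.  What this does *not* emulate about real
RNA-seq is documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .references import IsoformPair

__all__ = [
    "SimulationConfig",
    "GroupDesign",
    "CohortDesign",
    "TruthRecord",
    "FastqRead",
    "simulate_sample_reads",
    "simulate_cohort",
    "draw_fractions",
    "rosmap_like_design",
    "write_fastq",
    "read_fastq",
    "reverse_complement",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    sequence: str
    quality: str


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read (kept out of the FASTQ on purpose)."""

    read_id: str
    source_isoform: str  # 'canonical' | 'skipped'
    source_start: int  # 0-based on the source transcript
    n_substitutions: int
    spans_window: bool
    strand: str = "+"


@dataclass(frozen=True)
class SimulationConfig:
    """Per-sample read-generation settings.

    ``true_fraction_skipped`` is the proportion of transcript molecules that
    are the exon-skipped isoform; each read picks its source isoform by an
    independent Bernoulli draw of that probability.  ``substitution_rate`` is
    the per-base error probability (substitution to a uniformly chosen
    different base).  ``both_strands`` flips each read to the reverse
    complement with probability one half, for exercising orientation
    handling; default is forward-only.
    """

    true_fraction_skipped: float
    n_reads: int
    read_length: int = 75
    substitution_rate: float = 0.0
    seed: int = 0
    paired: bool = False
    both_strands: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_fraction_skipped <= 1.0:
            raise ValueError("true_fraction_skipped must be in [0, 1]")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must be in [0, 1)")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.read_length < 2:
            raise ValueError("read_length must be >= 2")


def _mutate(seq_arr: np.ndarray, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    if rate <= 0:
        return seq_arr, 0
    hits = np.nonzero(rng.random(seq_arr.size) < rate)[0]
    if hits.size == 0:
        return seq_arr, 0
    out = seq_arr.copy()
    # substitute with a uniformly chosen *different* base
    shift = rng.integers(1, 4, size=hits.size)
    idx = np.searchsorted(_BASES, out[hits])
    out[hits] = _BASES[(idx + shift) % 4]
    return out, int(hits.size)


def simulate_sample_reads(
    pair: IsoformPair, config: SimulationConfig
) -> tuple[list[FastqRead], list[TruthRecord]]:
    """Draw reads from the two-isoform mixture; deterministic given the seed.

    Returns FASTQ records (constant quality ``I``) and one truth record per
    read.  Read IDs are opaque serial numbers so the classifier cannot learn
    anything from them.
    """
    seqs = {
        "canonical": pair.canonical.sequence,
        "skipped": pair.skipped.sequence,
    }
    rl = config.read_length
    shorter = min(len(s) for s in seqs.values())
    if rl > shorter:
        raise ValueError(
            f"read_length {rl} exceeds the shorter transcript ({shorter} nt)"
        )
    arrs = {k: np.frombuffer(v.encode(), dtype=np.uint8) for k, v in seqs.items()}
    rng = np.random.default_rng(config.seed)
    n = config.n_reads
    is_skipped = rng.random(n) < config.true_fraction_skipped
    # uniform start such that the read fits on its source transcript
    starts = np.empty(n, dtype=np.int64)
    for key, mask in (("canonical", ~is_skipped), ("skipped", is_skipped)):
        m = int(mask.sum())
        starts[mask] = rng.integers(0, len(seqs[key]) - rl + 1, size=m)
    flip = (
        rng.random(n) < 0.5 if config.both_strands else np.zeros(n, dtype=bool)
    )
    window = pair.window
    reads: list[FastqRead] = []
    truth: list[TruthRecord] = []
    qual = "I" * rl
    for i in range(n):
        source = "skipped" if is_skipped[i] else "canonical"
        start = int(starts[i])
        frag = arrs[source][start : start + rl]
        frag, nsub = _mutate(frag, config.substitution_rate, rng)
        seq = frag.tobytes().decode()
        strand = "+"
        if flip[i]:
            seq = reverse_complement(seq)
            strand = "-"
        if window is None:
            spans = False
        else:
            jpos = pair.junction_pos(source)
            spans = (
                start <= window[0]
                and start + rl >= window[1]
                and window[0] < jpos < window[1]
            )
        rid = f"r{i:07d}"
        reads.append(FastqRead(rid, seq, qual))
        truth.append(TruthRecord(rid, source, start, nsub, spans, strand))
        if config.paired:
            # basic mate support: the mate is the reverse complement of the
            # same fragment (fragment length == read length); classified
            # independently downstream
            mate = reverse_complement(seq)
            reads.append(FastqRead(f"r{i:07d}/2", mate, qual))
            truth.append(
                TruthRecord(
                    f"r{i:07d}/2", source, start, nsub, spans,
                    "-" if strand == "+" else "+",
                )
            )
    return reads, truth


# --- cohort-level generation -------------------------------------------------


@dataclass(frozen=True)
class GroupDesign:
    """Zero-inflated Beta model for one diagnosis group's skipping fractions.

    With probability ``zero_inflation`` a sample has no skipped transcripts at
    all (true fraction exactly 0); otherwise the fraction is Beta(a, b).
    ``sex_freq``/``apoe_freq`` are per-group categorical frequencies.
    """

    n_samples: int
    zero_inflation: float
    beta_a: float
    beta_b: float
    sex_freq: dict[str, float] = field(
        default_factory=lambda: {"F": 0.5, "M": 0.5}
    )

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must be in [0, 1]")
        if abs(sum(self.sex_freq.values()) - 1.0) > 1e-9:
            raise ValueError("sex frequencies must sum to 1")


@dataclass(frozen=True)
class CohortDesign:
    """Mock case-control cohort: groups, metadata generators, read settings."""

    groups: dict[str, GroupDesign]
    apoe_freq: dict[str, float] = field(
        default_factory=lambda: _APOE_FREQ.copy()
    )
    age_mean: float = 85.0
    age_sd: float = 6.0
    age_range: tuple[float, float] = (70.0, 100.0)
    n_reads_per_sample: int = 1500
    read_length: int = 75
    substitution_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        if abs(sum(self.apoe_freq.values()) - 1.0) > 1e-9:
            raise ValueError("APOE frequencies must sum to 1")


# APOE genotype counts from the published cohort figure (22:5, 23:96, 24:16,
# 33:515, 34:171, 44:12), used as relative frequencies.
_APOE_FREQ = {
    "22": 5 / 815,
    "23": 96 / 815,
    "24": 16 / 815,
    "33": 515 / 815,
    "34": 171 / 815,
    "44": 12 / 815,
}


def rosmap_like_design(
    n_per_group: int = 60,
    seed: int = 0,
    *,
    null: bool = False,
    n_reads_per_sample: int = 1500,
) -> CohortDesign:
    """Cohort design emulating the published AD/NCI frontal-lobe study.

    Zero-inflation 0.15 (AD) and 0.52 (NCI) reproduce the reported splicing
    prevalences of 85% and 48%; the Beta components give the AD group a
    heavier-tailed nonzero fraction distribution.  Sex frequencies follow the
    published per-group counts (AD 210 F / 78 M, NCI 209 F / 117 M).  With
    ``null=True`` both groups use the NCI generating distribution, for
    calibration experiments.
    """
    ad = GroupDesign(
        n_samples=n_per_group,
        zero_inflation=0.15,
        beta_a=2.0,
        beta_b=8.0,
        sex_freq={"F": 210 / 288, "M": 78 / 288},
    )
    nci = GroupDesign(
        n_samples=n_per_group,
        zero_inflation=0.52,
        beta_a=1.5,
        beta_b=12.0,
        sex_freq={"F": 209 / 326, "M": 117 / 326},
    )
    if null:
        ad = GroupDesign(
            n_samples=n_per_group,
            zero_inflation=nci.zero_inflation,
            beta_a=nci.beta_a,
            beta_b=nci.beta_b,
            sex_freq=ad.sex_freq,
        )
    return CohortDesign(
        groups={"AD": ad, "NCI": nci},
        seed=seed,
        n_reads_per_sample=n_reads_per_sample,
    )


def draw_fractions(design: GroupDesign, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` per-sample true skipping fractions from the group model."""
    zero = rng.random(n) < design.zero_inflation
    frac = rng.beta(design.beta_a, design.beta_b, size=n)
    frac[zero] = 0.0
    return frac


def simulate_cohort(
    pair: IsoformPair,
    design: CohortDesign,
    out_dir: str | Path,
    *,
    write_read_truth: bool = False,
) -> pd.DataFrame:
    """Simulate a whole cohort: per-sample FASTQ files plus metadata/truth TSVs.

    Writes ``metadata.tsv`` (sample_id, group, sex, apoe, age, reads_path),
    ``truth.tsv`` (sample_id, group, true_fraction, n_reads) and one FASTQ per
    sample into ``out_dir``; returns the combined manifest as a DataFrame.
    Fully reproducible: the design seed is split into independent per-sample
    streams, so outputs are byte-identical across runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(design.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    rows = []
    sample_seeds: list[int] = []
    idx = 0
    for group, gdesign in design.groups.items():
        fractions = draw_fractions(gdesign, gdesign.n_samples, meta_rng)
        sexes = meta_rng.choice(
            list(gdesign.sex_freq), size=gdesign.n_samples, p=list(gdesign.sex_freq.values())
        )
        apoes = meta_rng.choice(
            list(design.apoe_freq), size=gdesign.n_samples, p=list(design.apoe_freq.values())
        )
        ages = np.clip(
            meta_rng.normal(design.age_mean, design.age_sd, size=gdesign.n_samples),
            *design.age_range,
        )
        for i in range(gdesign.n_samples):
            idx += 1
            sid = f"S{idx:04d}"
            rows.append(
                {
                    "sample_id": sid,
                    "group": group,
                    "sex": str(sexes[i]),
                    "apoe": str(apoes[i]),
                    "age": round(float(ages[i]), 1),
                    "true_fraction": float(fractions[i]),
                }
            )
    # per-sample read seeds drawn deterministically from the root sequence
    child_seqs = root.spawn(len(rows) + 1)[1:]
    for row, seq in zip(rows, child_seqs):
        sample_seed = int(seq.generate_state(1, dtype=np.uint32)[0] % (2**31))
        sample_seeds.append(sample_seed)
        config = SimulationConfig(
            true_fraction_skipped=row["true_fraction"],
            n_reads=design.n_reads_per_sample,
            read_length=design.read_length,
            substitution_rate=design.substitution_rate,
            seed=sample_seed,
        )
        reads, truth = simulate_sample_reads(pair, config)
        fastq_path = out / f"{row['sample_id']}.fastq"
        write_fastq(reads, fastq_path)
        row["reads_path"] = str(fastq_path)
        row["n_reads"] = len(reads)
        if write_read_truth:
            pd.DataFrame(truth).to_csv(
                out / f"{row['sample_id']}.truth.tsv", sep="\t", index=False
            )
    manifest = pd.DataFrame(rows)
    meta_cols = ["sample_id", "group", "sex", "apoe", "age", "reads_path"]
    # metadata carries file names relative to out_dir so that reruns into
    # different directories stay byte-identical; read_manifest resolves them
    portable = manifest[meta_cols].copy()
    portable["reads_path"] = [Path(p).name for p in portable["reads_path"]]
    portable.to_csv(out / "metadata.tsv", sep="\t", index=False)
    manifest[["sample_id", "group", "true_fraction", "n_reads"]].to_csv(
        out / "truth.tsv", sep="\t", index=False
    )
    return manifest


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> Iterable[tuple[str, str]]:
    """Yield (read_id, sequence) from a 4-line-record FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield header[1:].split()[0].strip(), seq
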