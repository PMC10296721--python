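"""Transcript exon models and canonical/exon-skipped isoform pairs.

The splicing event quantified by this package removes one internal exon from a
transcript (for BAX: exon 2, producing the mitochondria-targeting-deficient
Bax∆2 isoform).  Both isoforms share every other exon, so the only sequence
that distinguishes them is the exon junction created (or destroyed) by the
skip.  This module models the canonical transcript as an ordered set of exons
tiling the sequence, derives the skipped isoform from it, and records the
diagnostic junction window used downstream by the read classifier.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open.  Everything user-facing
(exon TSVs, window arguments, reports) is 1-based inclusive, which is the
convention used when the diagnostic window is quoted as "bases 30 to 40".
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "ExonModel",
    "IsoformPair",
    "ModelError",
    "load_reference",
    "build_skipped_isoform",
    "set_junction_window",
    "read_exon_tsv",
    "write_fasta",
    "fixture_pair",
    "bax_like_pair",
    "DEFAULT_WINDOW_1BASED",
]

#: Default diagnostic window (1-based inclusive) for the BAX references:
#: reads must overlap bases 30-40 on either isoform to count as junction
#: evidence.
DEFAULT_WINDOW_1BASED = (30, 40)

_VALID_BASES = frozenset("ACGTN")


class ModelError(ValueError):
    """Raised when an exon model or isoform pair violates its invariants."""


@dataclass(frozen=True)
class ExonModel:
    """A transcript sequence tiled exactly by an ordered list of exons.

    Parameters
    ----------
    transcript_id : str
        Label used as the FASTA/SAM reference name.
    sequence : str
        Nucleotide sequence over ``{A, C, G, T, N}`` (upper case).
    exons : tuple of (int, int)
        0-based half-open intervals, sorted, non-overlapping and contiguous:
        they must tile ``sequence`` exactly.
    labels : tuple of str
        One label per exon (``E1`` ... by default).
    """

    transcript_id: str
    sequence: str
    exons: tuple[tuple[int, int], ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ModelError(f"{self.transcript_id}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ModelError(
                f"{self.transcript_id}: invalid characters {sorted(bad)} in sequence"
            )
        if not self.exons:
            raise ModelError(f"{self.transcript_id}: exon list is empty")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"E{i + 1}" for i in range(len(self.exons)))
            )
        if len(self.labels) != len(self.exons):
            raise ModelError(f"{self.transcript_id}: one label required per exon")
        prev_end = 0
        for label, (start, end) in zip(self.labels, self.exons):
            if start >= end:
                raise ModelError(f"{self.transcript_id}: exon {label} is empty")
            if start > prev_end:
                # first untiled base, reported 1-based
                raise ModelError(
                    f"{self.transcript_id}: gap at base {prev_end + 1} "
                    f"(before exon {label})"
                )
            if start < prev_end:
                raise ModelError(
                    f"{self.transcript_id}: exon {label} overlaps the previous exon"
                )
            prev_end = end
        if prev_end != len(self.sequence):
            raise ModelError(
                f"{self.transcript_id}: exons cover {prev_end} bases but the "
                f"sequence has {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_sequence(self, index_1based: int) -> str:
        start, end = self.exons[index_1based - 1]
        return self.sequence[start:end]

    def exons_1based(self) -> list[tuple[str, int, int]]:
        """Render exons as (label, start, end), 1-based inclusive."""
        return [(lab, s + 1, e) for lab, (s, e) in zip(self.labels, self.exons)]


@dataclass(frozen=True)
class IsoformPair:
    """Canonical and exon-skipped isoforms plus the diagnostic junction window.

    ``junction_pos_*`` is the 0-based index of the first base *after* the
    diagnostic junction on each reference (equivalently, the number of bases
    preceding the junction).  For an exon-``k`` skip both junctions sit at the
    end of exon ``k−1``, so on the two references they share the same
    coordinate; this is what makes a single window (e.g. bases 30-40 for BAX)
    applicable to both.

    ``window`` is stored 0-based half-open, or ``None`` until set.
    """

    canonical: ExonModel
    skipped: ExonModel
    skipped_exon_index: int
    junction_pos_canonical: int
    junction_pos_skipped: int
    window: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        k = self.skipped_exon_index
        s, e = self.canonical.exons[k - 1]
        expected = self.canonical.sequence[:s] + self.canonical.sequence[e:]
        if self.skipped.sequence != expected:
            raise ModelError(
                "skipped isoform sequence is not the canonical sequence with "
                f"exon {self.canonical.labels[k - 1]} removed"
            )
        if self.window is not None:
            for name, jpos in (
                (self.canonical.transcript_id, self.junction_pos_canonical),
                (self.skipped.transcript_id, self.junction_pos_skipped),
            ):
                _check_window_diagnostic(self.window, jpos, name)

    @property
    def window_1based(self) -> Optional[tuple[int, int]]:
        if self.window is None:
            return None
        return (self.window[0] + 1, self.window[1])

    def junction_pos(self, reference: str) -> int:
        """Junction coordinate for ``reference`` in {'canonical', 'skipped'}."""
        if reference == "canonical":
            return self.junction_pos_canonical
        if reference == "skipped":
            return self.junction_pos_skipped
        raise KeyError(reference)

    def model(self, reference: str) -> ExonModel:
        if reference == "canonical":
            return self.canonical
        if reference == "skipped":
            return self.skipped
        raise KeyError(reference)

    def reference_names(self) -> dict[str, str]:
        return {
            self.canonical.transcript_id: "canonical",
            self.skipped.transcript_id: "skipped",
        }


def _check_window_diagnostic(window: tuple[int, int], jpos: int, name: str) -> None:
    """The window must include at least one base on each side of the junction."""
    w0, w1 = window
    if not (w0 < jpos < w1):
        raise ModelError(
            f"window bases {w0 + 1}-{w1} on {name} does not bracket the exon "
            f"junction after base {jpos}; it would not be diagnostic"
        )


def load_reference(
    fasta_path: str | Path,
    exon_intervals: Sequence[tuple[int, int]],
    *,
    record_id: Optional[str] = None,
    labels: Optional[Sequence[str]] = None,
) -> ExonModel:
    """Read a transcript FASTA and attach a validated exon model.

    ``exon_intervals`` are 1-based inclusive (the I/O convention).  The FASTA
    must contain exactly one record unless ``record_id`` selects one.  The
    sequence is upper-cased and RNA ``U`` is converted to ``T``.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ModelError(f"{fasta_path}: no FASTA records")
    if record_id is None:
        if len(records) > 1:
            raise ModelError(
                f"{fasta_path}: {len(records)} records; pass record_id to select one"
            )
        record = records[0]
    else:
        by_id = {r.id: r for r in records}
        if record_id not in by_id:
            raise ModelError(f"{fasta_path}: no record named {record_id!r}")
        record = by_id[record_id]
    seq = str(record.seq).upper().replace("U", "T")
    exons = tuple((s - 1, e) for s, e in exon_intervals)
    return ExonModel(
        transcript_id=record.id,
        sequence=seq,
        exons=exons,
        labels=tuple(labels) if labels else (),
    )


def build_skipped_isoform(
    canonical: ExonModel,
    skipped_exon_index: int,
    *,
    skipped_id: Optional[str] = None,
    expected_sequence: Optional[str] = None,
) -> IsoformPair:
    """Derive the exon-skipped isoform and pair it with the canonical one.

    ``skipped_exon_index`` is 1-based (skip exon 2 for the BAX case).  The
    skipped isoform's sequence is the concatenation of every other exon, so
    the pair differs by exactly that exon.  If ``expected_sequence`` is given
    (e.g. from a second FASTA) it is validated against the derived sequence.
    """
    k = skipped_exon_index
    if not 1 <= k <= canonical.n_exons:
        raise ModelError(
            f"skipped_exon_index {k} out of range 1..{canonical.n_exons}"
        )
    s, e = canonical.exons[k - 1]
    skipped_seq = canonical.sequence[:s] + canonical.sequence[e:]
    if expected_sequence is not None:
        expected = expected_sequence.upper().replace("U", "T")
        if expected != skipped_seq:
            raise ModelError(
                "supplied skipped-isoform sequence does not match the sequence "
                f"derived by removing exon {canonical.labels[k - 1]}"
            )
    removed = e - s
    new_exons = []
    new_labels = []
    for i, ((a, b), lab) in enumerate(zip(canonical.exons, canonical.labels), start=1):
        if i == k:
            continue
        if i < k:
            new_exons.append((a, b))
        else:
            new_exons.append((a - removed, b - removed))
        new_labels.append(lab)
    skipped = ExonModel(
        transcript_id=skipped_id or f"{canonical.transcript_id}_skip{canonical.labels[k - 1]}",
        sequence=skipped_seq,
        exons=tuple(new_exons),
        labels=tuple(new_labels),
    )
    # Both diagnostic junctions sit at the end of the exon preceding the
    # skipped exon (position 0 if the first exon is skipped).
    junction = canonical.exons[k - 1][0]
    return IsoformPair(
        canonical=canonical,
        skipped=skipped,
        skipped_exon_index=k,
        junction_pos_canonical=junction,
        junction_pos_skipped=junction,
    )


def set_junction_window(
    pair: IsoformPair,
    start_1based: Optional[int] = None,
    end_1based: Optional[int] = None,
) -> IsoformPair:
    """Attach the diagnostic window (1-based inclusive) to the pair.

    With no arguments the BAX default, bases 30-40, is applied.  The window
    must bracket the junction position on both references, otherwise reads
    could satisfy the overlap rule without crossing the junction and the
    window would not be diagnostic.
    """
    if start_1based is None and end_1based is None:
        start_1based, end_1based = DEFAULT_WINDOW_1BASED
    if start_1based is None or end_1based is None:
        raise ModelError("window start and end must be given together")
    if start_1based < 1 or start_1based > end_1based:
        raise ModelError(
            f"invalid window bases {start_1based}-{end_1based}: need 1 <= start <= end"
        )
    window = (start_1based - 1, end_1based)
    for name, jpos, model in (
        ("canonical", pair.junction_pos_canonical, pair.canonical),
        ("skipped", pair.junction_pos_skipped, pair.skipped),
    ):
        if window[1] > len(model):
            raise ModelError(
                f"window end {end_1based} beyond {name} reference "
                f"({len(model)} nt)"
            )
        _check_window_diagnostic(window, jpos, model.transcript_id)
    return dataclasses.replace(pair, window=window)


def read_exon_tsv(path: str | Path) -> tuple[list[tuple[int, int]], list[str]]:
    """Read a 3-column exon TSV (exon_label, start_1based, end_1based)."""
    intervals: list[tuple[int, int]] = []
    labels: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ModelError(f"{path}: expected 3 tab-separated columns: {line!r}")
            if fields[0].lower() in {"exon_label", "label"}:
                continue
            labels.append(fields[0])
            intervals.append((int(fields[1]), int(fields[2])))
    return intervals, labels


def write_fasta(models: Sequence[ExonModel], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.transcript_id}\n")
            for i in range(0, len(m.sequence), width):
                fh.write(m.sequence[i : i + width] + "\n")


def fixture_pair(window_1based: tuple[int, int] = (8, 13)) -> IsoformPair:
    """Tiny 3-exon toy pair used throughout the test suite and docs.

    Canonical ``ACGTACGTAC|GGGGCCCC|TTAATTAA`` (exons of 10/8/8 nt); skipping
    exon 2 yields ``ACGTACGTACTTAATTAA`` with the skip junction after base 10
    on both references.
    """
    canonical = ExonModel(
        transcript_id="toy_canonical",
        sequence="ACGTACGTACGGGGCCCCTTAATTAA",
        exons=((0, 10), (10, 18), (18, 26)),
    )
    pair = build_skipped_isoform(canonical, 2, skipped_id="toy_skipped")
    return set_junction_window(pair, *window_1based)


# Exon lengths for the synthetic BAX-like transcript.  Exon 1 ends at base 34
# so that the default diagnostic window (bases 30-40) brackets both the
# canonical E1|E2 junction and the skip E1|E3 junction.  Desk-scale stand-in:
# 220 nt total rather than the full-length BAX coding sequence, so junction
# coverage per simulated read stays high.
_BAX_LIKE_EXON_LENGTHS = (34, 50, 46, 30, 30, 30)


def bax_like_pair(seed: int = 20230610) -> IsoformPair:
    """Synthetic six-exon stand-in for the Baxα/Bax∆2 reference pair.

    The real references are controlled-access-adjacent GenBank entries; this
    synthetic pair reproduces their structure (six exons E1-E6, exon-2 skip,
    junction inside the bases 30-40 window) with a deterministic random
    sequence.  It is a synthetic fixture, not BAX sequence.
    """
    rng = np.random.default_rng(seed)
    sequence = "".join(rng.choice(list("ACGT"), size=sum(_BAX_LIKE_EXON_LENGTHS)))
    bounds = np.cumsum((0,) + _BAX_LIKE_EXON_LENGTHS)
    exons = tuple((int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:]))
    canonical = ExonModel(
        transcript_id="BAXalpha_like", sequence=sequence, exons=exons
    )
    pair = build_skipped_isoform(canonical, 2, skipped_id="BAXdelta2_like")
    pair = set_junction_window(pair)
    # the two junction contexts must be distinguishable or the pair is useless
    j = pair.junction_pos_canonical
    if pair.canonical.sequence[j : j + 6] == pair.skipped.sequence[j : j + 6]:
        raise ModelError("degenerate synthetic pair: junction contexts coincide")
    return pair
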