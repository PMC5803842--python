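"""CU-motif scanning of 3' UTRs and clustered PTB-binding-region detection.

A CU motif is a maximal run of contiguous pyrimidines of length >= ``min_len``
(default 3) that contains at least one cytosine and at least one uracil.
Maximality means the run cannot be extended by one position in either
direction without leaving the pyrimidine alphabet, so motifs never overlap
and are never double-counted.  T is treated as U (mRNA sense); IUPAC
ambiguity codes (including Y) are conservatively treated as non-pyrimidines
because they cannot be verified to contribute both base classes.

A putative PTB-binding region is a cluster of at least ``min_motifs``
(default 4) consecutive motifs spanning at most ``window`` nucleotides
(default 150) from the first motif's start to the last motif's end —
the clustering rule established for StPTB1/6 binding to potato StBEL5.
Overlapping qualifying windows are merged into the maximal run of motifs
each of whose ``min_motifs``-sized sub-windows qualifies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from ptbscan.errors import MoltypeError, ParameterError
from ptbscan.seq_io import SeqRecord

_PYRIMIDINE_RUN = re.compile(r"[CUT]+")


@dataclass(frozen=True)
class CUMotif:
    """One maximal CU run; 0-based half-open coordinates on the input UTR."""

    start: int
    end: int
    residues: str

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def span_1based(self) -> str:
        """1-based inclusive span for reports, e.g. '12-15'."""
        return f"{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class MotifReport:
    """Per-transcript CU-motif inventory (one Table-style row)."""

    seq_id: str
    utr_length: int
    motifs: tuple[CUMotif, ...]

    @property
    def count(self) -> int:
        return len(self.motifs)


@dataclass(frozen=True)
class BindingRegion:
    """A cluster of >= min_motifs consecutive CU motifs within the span window."""

    start: int
    end: int
    motif_indices: tuple[int, ...]

    @property
    def n_motifs(self) -> int:
        return len(self.motif_indices)


def scan_cu_motifs(record: SeqRecord, min_len: int = 3) -> MotifReport:
    """Report every maximal CU motif in a nucleotide record, left to right.

    The scan is strand-specific (the given mRNA-sense strand only) and
    invariant under T<->U spelling.  An empty report (count 0) is returned
    for sequences with no qualifying run.
    """
    if record.moltype != "nucleotide":
        raise MoltypeError(f"scan_cu_motifs expects a nucleotide record, got protein {record.id!r}")
    if min_len < 2:
        raise ParameterError(f"min_len must be >= 2, got {min_len}")
    seq = record.residues.replace("T", "U")
    motifs = []
    for m in _PYRIMIDINE_RUN.finditer(seq):
        run = m.group(0)
        if len(run) >= min_len and "C" in run and "U" in run:
            motifs.append(CUMotif(start=m.start(), end=m.end(), residues=run))
    return MotifReport(seq_id=record.id, utr_length=len(seq), motifs=tuple(motifs))


def find_binding_regions(
    report: MotifReport,
    window: int = 150,
    min_motifs: int = 4,
    span_mode: str = "start_to_end",
) -> list[BindingRegion]:
    """Detect clusters of consecutive CU motifs dense enough for PTB binding.

    A base window is ``min_motifs`` consecutive motifs whose span (first
    motif start to last motif end by default; first-start to last-start with
    ``span_mode='start_to_start'``) is at most ``window`` nucleotides.
    Chains of overlapping qualifying base windows are merged into one
    maximal region.
    """
    if window <= 0:
        raise ParameterError(f"window must be positive, got {window}")
    if min_motifs < 1:
        raise ParameterError(f"min_motifs must be >= 1, got {min_motifs}")
    if span_mode not in ("start_to_end", "start_to_start"):
        raise ParameterError(f"unknown span_mode {span_mode!r}")
    motifs = report.motifs
    n = len(motifs)
    if n < min_motifs:
        return []

    def _span(i: int, j: int) -> int:  # motifs i..j inclusive
        if span_mode == "start_to_start":
            return motifs[j].start - motifs[i].start
        return motifs[j].end - motifs[i].start

    qualifies = [_span(i, i + min_motifs - 1) <= window for i in range(n - min_motifs + 1)]
    regions: list[BindingRegion] = []
    i = 0
    while i < len(qualifies):
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(qualifies) and qualifies[j + 1]:
            j += 1
        first, last = i, j + min_motifs - 1
        regions.append(
            BindingRegion(
                start=motifs[first].start,
                end=motifs[last].end,
                motif_indices=tuple(range(first, last + 1)),
            )
        )
        i = j + 1
    return regions


def report_to_dict(report: MotifReport) -> dict:
    """JSON-serializable form of a motif report (0-based spans, residues kept)."""
    return {
        "seq_id": report.seq_id,
        "utr_length": report.utr_length,
        "motifs": [{"start": m.start, "end": m.end, "residues": m.residues} for m in report.motifs],
    }


def report_from_dict(d: dict) -> MotifReport:
    """Inverse of :func:`report_to_dict`."""
    return MotifReport(
        seq_id=d["seq_id"],
        utr_length=int(d["utr_length"]),
        motifs=tuple(CUMotif(int(m["start"]), int(m["end"]), m["residues"]) for m in d["motifs"]),
    )


def tabulate_motifs(reports: list[MotifReport]) -> pd.DataFrame:
    """One row per transcript: seq_id, UTR length (nt), motif count, 1-based spans.

    Row order follows input order, mirroring a per-transcript survey table.
    """
    if not reports:
        raise ParameterError("tabulate_motifs needs at least one report")
    return pd.DataFrame(
        {
            "seq_id": [r.seq_id for r in reports],
            "utr_length_nt": [r.utr_length for r in reports],
            "n_cu_motifs": [r.count for r in reports],
            "motif_spans": [";".join(m.span_1based for m in r.motifs) for r in reports],
        }
    )
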