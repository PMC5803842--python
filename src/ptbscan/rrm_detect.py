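"""RRM/RNP domain location in candidate PTB proteins and PTB-type calling.

Plant PTB proteins carry RNA-recognition motifs (RRMs) of roughly 90 amino
acids, each containing two short ribonucleoprotein boxes (RNP2 then RNP1,
6-8 residues) that contact the RNA.  Chaperone-clade PTBs (PTB1/6 type,
the CmRBP50 family) carry four RRMs; splicing-associated PTB7-type proteins
carry three.

Detection is reference-based, mirroring how surveys annotate candidate
orthologues: each of four reference RRM profiles is locally aligned to the
query (BLOSUM62, affine gaps); hits passing identity and profile-coverage
thresholds are assigned greedily by score without query overlap, and the
RNP boxes are mapped through the alignment into query coordinates.  The
qualifying-hit count then gives the 4-vs-3 type call.

The packaged default profile set (``data/rrm_profiles_synthetic.fasta``) is
a synthetic stand-in: four constructed RRM-like blocks with canonical RNP
placement, intended for pipeline operation and recovery experiments.  For
annotation of real proteins, substitute profiles cut from an experimentally
anchored PTB (e.g. CmRBP50 or StPTB1) via ``load_profiles``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

from ptbscan.errors import FormatError, MoltypeError, ParameterError
from ptbscan.orthology import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    DEFAULT_MATRIX,
    LocalAlignment,
    local_align,
)
from ptbscan.seq_io import SeqRecord, read_fasta

logger = logging.getLogger(__name__)

PROFILE_NAMES = ("RRM1", "RRM2", "RRM3", "RRM4")


@dataclass(frozen=True)
class RRMProfile:
    """A reference RRM block with the offsets of its two RNP boxes.

    ``rnp2`` precedes ``rnp1`` in sequence (RNP2 sits on the first beta
    strand, RNP1 on the third).  Spans are 0-based half-open offsets within
    the profile.
    """

    name: str
    residues: str
    rnp1: tuple[int, int]
    rnp2: tuple[int, int]

    def __post_init__(self) -> None:
        if not 60 <= len(self.residues) <= 120:
            raise ParameterError(
                f"profile {self.name}: length {len(self.residues)} outside the 60-120 aa RRM range"
            )
        for label, (s, e) in (("rnp1", self.rnp1), ("rnp2", self.rnp2)):
            if not (0 <= s < e <= len(self.residues)):
                raise ParameterError(f"profile {self.name}: {label} span {s}:{e} outside profile")
            if not 6 <= e - s <= 8:
                raise ParameterError(f"profile {self.name}: {label} length {e - s} outside 6-8 aa")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RRMHit:
    """One located RRM on the query; RNP spans are query coordinates.

    An RNP span is ``None`` when it could not be mapped (deleted in the
    query); ``*_flagged`` marks spans widened or shortened by indels.
    """

    profile_name: str
    query_span: tuple[int, int]
    identity_pct: float
    score: float
    rnp1_span: tuple[int, int] | None = None
    rnp2_span: tuple[int, int] | None = None
    rnp1_flagged: bool = False
    rnp2_flagged: bool = False
    alignment: LocalAlignment | None = None


@dataclass(frozen=True)
class PTBClass:
    """The RRM-count-based type call for one protein."""

    seq_id: str
    n_rrms: int
    call: str  # "PTB1/6-type" | "PTB7-type" | "unclassified"


def load_profiles(path: str | Path) -> list[RRMProfile]:
    """Load RRM profiles from FASTA with ``rnp1=off:len rnp2=off:len`` header tags."""
    records = read_fasta(path, moltype="protein")
    profiles = []
    for rec in records:
        tags = dict(
            item.split("=", 1) for item in rec.description.split() if "=" in item
        )
        try:
            spans = {}
            for key in ("rnp1", "rnp2"):
                off, ln = tags[key].split(":")
                spans[key] = (int(off), int(off) + int(ln))
        except (KeyError, ValueError) as exc:
            raise FormatError(
                f"profile {rec.id}: header must carry rnp1=offset:len and rnp2=offset:len ({exc})"
            ) from exc
        profiles.append(RRMProfile(name=rec.id, residues=rec.residues, rnp1=spans["rnp1"], rnp2=spans["rnp2"]))
    return profiles


def default_profiles() -> list[RRMProfile]:
    """The packaged synthetic RRM1-RRM4 profile set."""
    ref = resources.files("ptbscan").joinpath("data/rrm_profiles_synthetic.fasta")
    with resources.as_file(ref) as path:
        return load_profiles(path)


def _map_profile_span(aln: LocalAlignment, span: tuple[int, int]) -> tuple[tuple[int, int] | None, bool]:
    """Map a profile-coordinate span through the alignment to query coordinates.

    Returns (query_span, flagged); flagged when indels widen or truncate
    the mapped box, None when the whole box falls in a deletion.
    """
    s, e = span
    mapped = []
    for (ps, pe), (qs, _qe) in zip(aln.a_blocks, aln.b_blocks):
        lo, hi = max(s, ps), min(e, pe)
        if lo < hi:
            mapped.extend(qs + (p - ps) for p in range(lo, hi))
    if not mapped:
        return None, True
    qspan = (min(mapped), max(mapped) + 1)
    flagged = len(mapped) < (e - s) or (qspan[1] - qspan[0]) > len(mapped)
    return qspan, flagged


def detect_rnps(hit: RRMHit, profile: RRMProfile) -> RRMHit:
    """Fill in the query-coordinate RNP1/RNP2 spans of a located RRM.

    Requires the hit's retained alignment (as produced by
    :func:`locate_rrms`).
    """
    if hit.alignment is None:
        raise ParameterError(f"hit for {hit.profile_name} has no retained alignment")
    rnp1, f1 = _map_profile_span(hit.alignment, profile.rnp1)
    rnp2, f2 = _map_profile_span(hit.alignment, profile.rnp2)
    return replace(hit, rnp1_span=rnp1, rnp2_span=rnp2, rnp1_flagged=f1, rnp2_flagged=f2)


def locate_rrms(
    query: SeqRecord,
    profiles: list[RRMProfile] | None = None,
    min_identity: float = 40.0,
    min_cover: float = 0.6,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[RRMHit]:
    """Locate RRM domains on a protein query using reference profiles.

    Each profile's best local alignment to the query is kept if it reaches
    ``min_identity`` percent identity and covers at least ``min_cover`` of
    the profile; surviving hits are assigned greedily by descending score
    (ties: earlier query start, then profile order) with no query overlap.
    Hits are returned in query-coordinate order; out-of-order profiles
    (e.g. RRM3 before RRM2 on the query) are reported with a warning, never
    reordered.
    """
    if query.moltype != "protein":
        raise MoltypeError(f"locate_rrms expects a protein query, got {query.id!r}")
    if profiles is None:
        profiles = default_profiles()
    if not 0 <= min_identity <= 100:
        raise ParameterError(f"min_identity must be in [0,100], got {min_identity}")
    if not 0 < min_cover <= 1:
        raise ParameterError(f"min_cover must be in (0,1], got {min_cover}")

    candidates = []
    for idx, prof in enumerate(profiles):
        prof_rec = SeqRecord(id=prof.name, residues=prof.residues, moltype="protein")
        aln = local_align(prof_rec, query, matrix, gap_open, gap_extend)
        if aln.is_empty:
            continue
        identity = 100 * aln.n_identical / aln.n_columns
        cover = (aln.a_span[1] - aln.a_span[0]) / len(prof)
        if identity < min_identity or cover < min_cover:
            continue
        hit = RRMHit(
            profile_name=prof.name,
            query_span=aln.b_span,
            identity_pct=identity,
            score=aln.score,
            alignment=aln,
        )
        candidates.append((idx, detect_rnps(hit, prof)))

    # greedy non-overlap assignment by descending score
    accepted: list[tuple[int, RRMHit]] = []
    for idx, hit in sorted(candidates, key=lambda t: (-t[1].score, t[1].query_span[0], t[0])):
        if any(hit.query_span[0] < h.query_span[1] and h.query_span[0] < hit.query_span[1] for _, h in accepted):
            continue
        accepted.append((idx, hit))
    accepted.sort(key=lambda t: t[1].query_span[0])
    profile_order = [idx for idx, _ in accepted]
    if profile_order != sorted(profile_order):
        logger.warning(
            "%s: RRM hits not collinear with the profile order (query order: %s)",
            query.id,
            [h.profile_name for _, h in accepted],
        )
    return [h for _, h in accepted]


def classify_ptb(seq_id: str, hits: list[RRMHit]) -> PTBClass:
    """Apply the RRM-count rule: 4 RRMs -> PTB1/6-type, 3 -> PTB7-type."""
    n = len(hits)
    if n == 4:
        call = "PTB1/6-type"
    elif n == 3:
        call = "PTB7-type"
    else:
        call = "unclassified"
    return PTBClass(seq_id=seq_id, n_rrms=n, call=call)
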