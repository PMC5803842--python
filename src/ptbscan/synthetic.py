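"""Seeded generators with planted ground truth for every pipeline stage.

Each generator is deterministic in (parameters, seed) and serializes its
planted truth next to the data, so in the noise-free limit every downstream
stage's output equals the truth exactly:

* :func:`gen_utr` — purine-biased 3' UTR backgrounds with a specified number
  of planted CU motifs (valid maximal runs), emulating the 74-503 nt UTRs
  with 2-20 motifs seen across BEL5/POTH1-like transcripts.
* :func:`gen_ptb_protein` — PTB-like proteins assembled from reference RRM
  blocks joined by random linkers, with i.i.d. substitutions, emulating
  4-RRM (PTB1/6-type) vs 3-RRM (PTB7-type) architectures.
* :func:`gen_ct_table` — replicated qPCR Ct tables with planted fold
  changes and Gaussian Ct noise (three biological x three technical
  replicates by default, GAPDH-style constant reference).
* :func:`gen_additive_tree` — random trees with positive branch lengths and
  their exact additive path-distance matrices (oracle input for NJ).

A single global seed fans out to independent per-component streams via
``numpy`` SeedSequence spawning, so adding a call for one component never
perturbs another's draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from ptbscan.errors import ParameterError
from ptbscan.rrm_detect import RRMProfile
from ptbscan.seq_io import SeqRecord

# fixed spawn keys per component: independent streams from one global seed
_STREAMS = {"utr": 0, "protein": 1, "ct": 2, "tree": 3}

PURINES = "AG"
AA20 = "ACDEFGHIKLMNPQRSTVWY"


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component RNG stream derived from one global seed."""
    if component not in _STREAMS:
        raise ParameterError(f"unknown component {component!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[component],))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class PlantedTruth:
    """Generator parameters plus planted feature coordinates/values."""

    kind: str
    params: dict
    features: dict

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "params": self.params, "features": self.features}, indent=2)


def _random_motif(rng: np.random.Generator, length: int) -> str:
    """A valid CU run: length >= 3 pyrimidines with at least one C and one U."""
    bases = rng.choice(list("CU"), size=length)
    if "C" not in bases:
        bases[rng.integers(length)] = "C"
    elif "U" not in bases:
        bases[rng.integers(length)] = "U"
    return "".join(bases)


def gen_utr(
    length: int,
    n_motifs: int,
    motif_len_range: tuple[int, int] = (3, 8),
    min_gap: int = 1,
    pyrimidine_background: float = 0.3,
    seed: int = 0,
) -> tuple[SeqRecord, PlantedTruth]:
    """A synthetic 3' UTR with exactly ``n_motifs`` planted CU motifs.

    The background is purine-biased (default 30% pyrimidine); any accidental
    valid CU run arising in the background is broken by resampling one of
    its pyrimidines to a purine, and the positions flanking each planted
    motif are forced to purines, so the motif scanner finds exactly the
    planted motifs.
    """
    if not 0 <= pyrimidine_background < 1:
        raise ParameterError("pyrimidine_background must be in [0,1)")
    if min_gap < 1:
        raise ParameterError("min_gap must be >= 1 (motifs must stay maximal)")
    lo, hi = motif_len_range
    if lo < 3:
        raise ParameterError("planted motifs must be at least 3 nt")
    rng = component_rng(seed, "utr")
    motif_lens = [int(rng.integers(lo, hi + 1)) for _ in range(n_motifs)]
    needed = sum(motif_lens) + max(0, n_motifs - 1) * min_gap
    if needed > length:
        raise ParameterError(
            f"cannot pack {n_motifs} motifs of total {sum(motif_lens)} nt plus gaps into {length} nt"
        )
    # distribute the spare background among the n_motifs+1 gaps
    spare = length - needed
    cuts = np.sort(rng.integers(0, spare + 1, size=n_motifs)) if n_motifs else np.array([], dtype=int)
    gap_extra = np.diff(np.concatenate(([0], cuts, [spare])))
    spans: list[tuple[int, int]] = []
    pos = 0
    seq: list[str] = []

    def _background(k: int) -> str:
        if k <= 0:
            return ""
        draws = rng.random(k)
        out = [
            (rng.choice(list("CU")) if d < pyrimidine_background else rng.choice(list(PURINES)))
            for d in draws
        ]
        return "".join(out)

    for i in range(n_motifs):
        gap = int(gap_extra[i]) + (min_gap if i > 0 else 0)
        chunk = _background(gap)
        # positions adjacent to a planted motif must be purines (maximality)
        if chunk:
            if i > 0:
                chunk = rng.choice(list(PURINES)) + chunk[1:]
            chunk = chunk[:-1] + rng.choice(list(PURINES))
        seq.append(chunk)
        pos += len(chunk)
        motif = _random_motif(rng, motif_lens[i])
        spans.append((pos, pos + len(motif)))
        seq.append(motif)
        pos += len(motif)
    tail = _background(int(gap_extra[-1]) if n_motifs else length)
    if tail and n_motifs:
        tail = rng.choice(list(PURINES)) + tail[1:]
    seq.append(tail)
    residues = list("".join(seq))
    assert len(residues) == length

    planted = set()
    for s, e in spans:
        planted.update(range(s, e))
    # break accidental valid runs in the background (rejection repair)
    from ptbscan.cu_motif import scan_cu_motifs  # local import to avoid a cycle

    while True:
        rec = SeqRecord(id=f"synthetic_utr_seed{seed}", residues="".join(residues), moltype="nucleotide")
        extra = [m for m in scan_cu_motifs(rec, min_len=3).motifs if (m.start, m.end) not in spans]
        if not extra:
            break
        for m in extra:
            bg_positions = [p for p in range(m.start, m.end) if p not in planted]
            p = bg_positions[int(rng.integers(len(bg_positions)))]
            residues[p] = rng.choice(list(PURINES))
    truth = PlantedTruth(
        kind="utr",
        params={
            "length": length,
            "n_motifs": n_motifs,
            "motif_len_range": list(motif_len_range),
            "min_gap": min_gap,
            "pyrimidine_background": pyrimidine_background,
            "seed": seed,
        },
        features={"motif_spans": [list(s) for s in spans]},
    )
    return rec, truth


def gen_ptb_protein(
    profiles: Sequence[RRMProfile],
    n_rrms: int,
    linker_len_range: tuple[int, int] = (15, 40),
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> tuple[SeqRecord, PlantedTruth]:
    """A synthetic PTB-like protein: the first ``n_rrms`` profiles joined by linkers.

    i.i.d. substitutions are applied at ``mutation_rate`` across the whole
    sequence; the planted (pre-mutation) RRM spans are recorded in the
    truth.  ``n_rrms`` in {3, 4} mirrors the PTB7-type vs PTB1/6-type
    architectures.
    """
    if not 0 <= mutation_rate < 0.5:
        raise ParameterError("mutation_rate must be in [0, 0.5)")
    if not 1 <= n_rrms <= len(profiles):
        raise ParameterError(f"n_rrms must be in [1, {len(profiles)}]")
    rng = component_rng(seed, "protein")
    lo, hi = linker_len_range
    parts: list[str] = []
    spans: list[tuple[int, int]] = []
    pos = 0
    for i in range(n_rrms):
        linker = "".join(rng.choice(list(AA20), size=int(rng.integers(lo, hi + 1))))
        parts.append(linker)
        pos += len(linker)
        block = profiles[i].residues
        spans.append((pos, pos + len(block)))
        parts.append(block)
        pos += len(block)
    tail = "".join(rng.choice(list(AA20), size=int(rng.integers(lo, hi + 1))))
    parts.append(tail)
    residues = list("".join(parts))
    if mutation_rate > 0:
        hits = rng.random(len(residues)) < mutation_rate
        for p in np.flatnonzero(hits):
            choices = [a for a in AA20 if a != residues[p]]
            residues[p] = choices[int(rng.integers(len(choices)))]
    rec = SeqRecord(id=f"synthetic_ptb_{n_rrms}rrm_seed{seed}", residues="".join(residues), moltype="protein")
    truth = PlantedTruth(
        kind="protein",
        params={
            "n_rrms": n_rrms,
            "linker_len_range": list(linker_len_range),
            "mutation_rate": mutation_rate,
            "seed": seed,
        },
        features={
            "rrm_spans": [list(s) for s in spans],
            "profile_names": [profiles[i].name for i in range(n_rrms)],
            "expected_call": {4: "PTB1/6-type", 3: "PTB7-type"}.get(n_rrms, "unclassified"),
        },
    )
    return rec, truth


def gen_ct_table(
    genes: Sequence[str],
    conditions: Sequence[str],
    true_folds: dict[str, dict[str, float]],
    reference_gene: str = "GAPDH",
    ct_base: float = 22.0,
    reference_ct: float = 18.0,
    noise_sd: float = 0.2,
    n_bio: int = 3,
    n_tech: int = 3,
    seed: int = 0,
):
    """A replicated qPCR Ct table with planted fold changes.

    The first condition is the calibrator (fold 1 for every gene).  Each Ct
    measurement is base - log2(fold) + N(0, noise_sd) noise, drawn i.i.d.
    per technical measurement; the reference gene is constant up to the
    same noise.  Returns (pandas DataFrame, PlantedTruth).
    """
    import pandas as pd

    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    calibrator = conditions[0]
    rng = component_rng(seed, "ct")
    rows = []
    for gene in list(genes) + [reference_gene]:
        for cond in conditions:
            if gene == reference_gene:
                mean_ct = reference_ct
            else:
                fold = 1.0 if cond == calibrator else float(true_folds[gene][cond])
                if fold <= 0:
                    raise ParameterError(f"fold for {gene}/{cond} must be > 0")
                mean_ct = ct_base - math.log2(fold)
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    ct = mean_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    rows.append((gene, cond, b, t, ct))
    table = pd.DataFrame(rows, columns=["gene", "condition", "bio_rep", "tech_rep", "ct"])
    truth = PlantedTruth(
        kind="ct",
        params={
            "genes": list(genes),
            "conditions": list(conditions),
            "reference_gene": reference_gene,
            "ct_base": ct_base,
            "noise_sd": noise_sd,
            "n_bio": n_bio,
            "n_tech": n_tech,
            "seed": seed,
        },
        features={"true_folds": {g: dict(v) for g, v in true_folds.items()}, "calibrator": calibrator},
    )
    return table, truth


def gen_additive_tree(
    n_taxa: int,
    branch_range: tuple[float, float] = (0.05, 1.0),
    seed: int = 0,
) -> tuple[TreeNode, DistanceMatrix, PlantedTruth]:
    """A random unrooted binary tree and its exact additive distance matrix.

    Built by sequentially attaching each new leaf to a uniformly chosen
    existing edge; branch lengths are uniform in ``branch_range``.  The
    matrix contains exact path distances, so NJ must reconstruct the tree
    (topology and lengths) exactly.
    """
    if n_taxa < 3:
        raise ParameterError("gen_additive_tree needs n_taxa >= 3")
    lo, hi = branch_range
    if lo <= 0:
        raise ParameterError("branch lengths must be positive")
    rng = component_rng(seed, "tree")

    def blen() -> float:
        return float(rng.uniform(lo, hi))

    labels = [f"T{i+1}" for i in range(n_taxa)]
    # adjacency over node ids; leaves are labels, internal nodes are ints
    adj: dict = {}
    next_internal = [0]

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    center = "I0"
    next_internal[0] = 1
    for leaf in labels[:3]:
        connect(center, leaf, blen())
    edges = [(center, leaf) for leaf in labels[:3]]
    for leaf in labels[3:]:
        u, v = edges[int(rng.integers(len(edges)))]
        w = adj[u][v]
        split = f"I{next_internal[0]}"
        next_internal[0] += 1
        frac = float(rng.uniform(0.2, 0.8))
        del adj[u][v]
        del adj[v][u]
        connect(u, split, w * frac)
        connect(split, v, w * (1 - frac))
        connect(split, leaf, blen())
        edges.remove((u, v))
        edges.extend([(u, split), (split, v), (split, leaf)])

    # exact path distances between leaves (upper triangle mirrored so the
    # matrix is exactly symmetric despite float summation order)
    mat = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        dist = {a: 0.0}
        stack = [a]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for j, b in enumerate(labels):
            if j > i:
                mat[i, j] = mat[j, i] = dist[b]
    dm = DistanceMatrix(mat, ids=labels)

    # build a skbio TreeNode rooted (trifurcating) at the original center
    def build(node, parent) -> TreeNode:
        tn = TreeNode(name=node if isinstance(node, str) and node in labels else None)
        for child, w in adj[node].items():
            if child == parent:
                continue
            sub = build(child, node)
            sub.length = w
            tn.append(sub)
        return tn

    tree = build(center, None)
    truth = PlantedTruth(
        kind="tree",
        params={"n_taxa": n_taxa, "branch_range": [lo, hi], "seed": seed},
        features={"labels": labels},
    )
    return tree, dm, truth
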