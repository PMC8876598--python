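"""Toxin family grouping by sequence homology and framework compatibility.

Mature toxins are clustered by single linkage over a two-track relation:
two peptides join the same family when their global-alignment identity
reaches a strict threshold, or when a relaxed identity threshold is met
and their cysteine frameworks are nearly identical.  Family labels
(A, B, C, ...) are positional — assigned in decreasing family-size order —
not claims of biological orthology.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .annotate import evalue_from_score, local_align
from .framework import CysteineFramework, framework_distance
from .seqio import ReferenceEntry

DEFAULT_IDENTITY_THRESHOLD = 40.0
DEFAULT_RELAXED_IDENTITY = 25.0
DEFAULT_FRAMEWORK_MAX_DIST = 1


@dataclass
class FamilyAssignment:
    toxin_name: str
    family_label: str
    subcluster: int = 0
    linkage_identity_pct: float = 0.0


def _global_aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "global"
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -12.0
    aln.extend_gap_score = -1.0
    return aln


def global_identity(a: str, b: str, _aligner: PairwiseAligner | None = None) -> float:
    """Percent identity over the columns of the best global alignment."""
    if a == b:
        return 100.0
    if not a or not b:
        return 0.0
    aligner = _aligner or _global_aligner()
    best = aligner.align(a, b)[0]
    counts = best.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / ncols if ncols else 0.0


def pairwise_identity_matrix(matures: list[str]) -> np.ndarray:
    """Symmetric matrix of global-alignment identities (diagonal 100)."""
    if not matures:
        raise ValueError("need at least one sequence")
    n = len(matures)
    aligner = _global_aligner()
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_identity(matures[i], matures[j], _aligner=aligner)
            mat[i, j] = mat[j, i] = ident
    return mat


def _family_labels() -> list[str]:
    """A..Z then AA, AB, ... (spreadsheet-style)."""
    labels = list(string.ascii_uppercase)
    labels += [a + b for a in string.ascii_uppercase for b in string.ascii_uppercase]
    return labels


def assign_families(precursors: list, frameworks: list[CysteineFramework],
                    identity_threshold_pct: float = DEFAULT_IDENTITY_THRESHOLD,
                    relaxed_identity_pct: float = DEFAULT_RELAXED_IDENTITY,
                    framework_max_dist: int = DEFAULT_FRAMEWORK_MAX_DIST,
                    identity_matrix: np.ndarray | None = None
                    ) -> list[FamilyAssignment]:
    """Single-linkage family assignment over mature peptides.

    ``precursors`` supplies (name, mature sequence) via objects with
    ``name``/``mature_seq`` attributes or plain (name, mature) tuples,
    aligned index-wise with ``frameworks``.  Two toxins are linked when
    identity >= identity_threshold_pct, or identity >= relaxed_identity_pct
    and framework_distance <= framework_max_dist.  Labels are assigned in
    descending family-size order, ties by smallest member name.
    """
    names, matures = [], []
    for p in precursors:
        if isinstance(p, tuple):
            names.append(p[0]); matures.append(p[1])
        else:
            names.append(p.name); matures.append(p.mature_seq)
    if len(names) != len(frameworks):
        raise ValueError("precursors and frameworks must align index-wise")
    n = len(names)
    if n == 0:
        return []
    # canonical order for input-order invariance
    order = sorted(range(n), key=lambda i: names[i])
    if identity_matrix is None:
        ident = pairwise_identity_matrix(matures)
    else:
        ident = np.asarray(identity_matrix, dtype=float)

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    link_identity = {i: 0.0 for i in range(n)}
    for a_idx in range(n):
        for b_idx in range(a_idx + 1, n):
            i, j = order[a_idx], order[b_idx]
            pid = ident[i, j]
            linked = pid >= identity_threshold_pct
            if not linked and pid >= relaxed_identity_pct:
                linked = framework_distance(frameworks[i], frameworks[j]) <= framework_max_dist
            if linked:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
                link_identity[i] = max(link_identity[i], pid)
                link_identity[j] = max(link_identity[j], pid)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    ordered_groups = sorted(
        groups.values(),
        key=lambda ms: (-len(ms), min(names[i] for i in ms)))
    labels = _family_labels()
    out: list[FamilyAssignment] = []
    for g_idx, members in enumerate(ordered_groups):
        label = labels[g_idx]
        for sub, i in enumerate(sorted(members, key=lambda i: names[i])):
            out.append(FamilyAssignment(
                toxin_name=names[i], family_label=label, subcluster=sub,
                linkage_identity_pct=round(link_identity[i], 2)))
    out.sort(key=lambda fa: fa.toxin_name)
    return out


def identity_histogram(queries: list[str], refs: list[ReferenceEntry],
                       bin_width_pct: float = 10.0,
                       evalue_cutoff: float = 1e-5) -> dict[str, int]:
    """Best-hit identity histogram of query peptides against a reference set.

    Each query contributes its best local-alignment hit identity to one
    bin [k*w, (k+1)*w); the top bin is closed at 100.  Queries with no
    hit passing the e-value cutoff land in the ``no-hit`` bin.  Bin
    counts always sum to the number of queries.
    """
    if not refs:
        raise ValueError("reference set must be non-empty")
    if bin_width_pct <= 0:
        raise ValueError("bin_width_pct must be positive")
    nbins = int(np.ceil(100.0 / bin_width_pct))
    edges = [i * bin_width_pct for i in range(nbins + 1)]
    labels = [f"{edges[i]:g}-{min(edges[i+1], 100):g}" for i in range(nbins)]
    hist = {lab: 0 for lab in labels}
    hist["no-hit"] = 0
    db_residues = sum(len(r.seq) for r in refs)
    for q in queries:
        best: tuple[float, float] | None = None  # (score, identity)
        for ref in refs:
            score, identity, _ = local_align(q, ref.seq)
            ev = evalue_from_score(score, len(q), db_residues)
            if ev > evalue_cutoff:
                continue
            if best is None or (score, identity) > best:
                best = (score, identity)
        if best is None:
            hist["no-hit"] += 1
        else:
            k = min(int(best[1] // bin_width_pct), nbins - 1)
            hist[labels[k]] += 1
    return hist
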