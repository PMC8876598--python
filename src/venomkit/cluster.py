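"""EST clustering into contigs/singletons and category bookkeeping.

ESTs of one annotation category are grouped by single-linkage transitive
closure of a pairwise overlap relation: two ESTs are linked when their best
local nucleotide alignment spans at least ``min_overlap_nt`` columns at
``min_identity_pct`` or better.  This reproduces the contig/singleton
structure an overlap assembler reports, without base-calling a consensus
(the longest member stands in as the contig representative).

Contig sizes are binned as singleton / 2-5 / 6-10 / 11-15 / 16-30 / >30,
with inclusive edges, and each contig additionally reports its number of
unique genes (distinct insert nucleotide sequences after poly-A trimming)
and unique proteins (distinct predicted precursor peptides).
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner

from .seqio import ESTRecord

DEFAULT_MIN_OVERLAP_NT = 100
DEFAULT_MIN_IDENTITY_PCT = 95.0

SIZE_BINS = ("singleton", "2-5", "6-10", "11-15", "16-30", ">30")


@dataclass
class Contig:
    id: str
    member_est_ids: list[str]
    consensus_nt: str = ""
    unique_gene_seqs: set[str] = field(default_factory=set)
    unique_protein_seqs: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.member_est_ids)

    @property
    def is_singleton(self) -> bool:
        return self.size == 1


@dataclass
class ClusterSet:
    category: str
    clusters: list[Contig]
    bins: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def n_singletons(self) -> int:
        return sum(1 for c in self.clusters if c.is_singleton)

    @property
    def n_contigs(self) -> int:
        return sum(1 for c in self.clusters if not c.is_singleton)

    @property
    def n_ests(self) -> int:
        return sum(c.size for c in self.clusters)


def size_bin(size: int) -> str:
    if size <= 1:
        return "singleton"
    if size <= 5:
        return "2-5"
    if size <= 10:
        return "6-10"
    if size <= 15:
        return "11-15"
    if size <= 30:
        return "16-30"
    return ">30"


def trim_polya(seq: str, min_run: int = 8) -> str:
    """Remove a terminal poly-A run of at least ``min_run`` bases."""
    return re.sub(r"A{%d,}$" % min_run, "", seq.upper())


def _dna_aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "local"
    aln.match_score = 1.0
    aln.mismatch_score = -2.0
    aln.open_gap_score = -4.0
    aln.extend_gap_score = -2.0
    return aln


def ests_overlap(a: str, b: str, min_overlap_nt: int = DEFAULT_MIN_OVERLAP_NT,
                 min_identity_pct: float = DEFAULT_MIN_IDENTITY_PCT,
                 _aligner: PairwiseAligner | None = None) -> bool:
    """True when the best local alignment of a and b satisfies the overlap rule."""
    if a == b:
        return True
    aligner = _aligner or _dna_aligner()
    alignments = aligner.align(a, b)
    if alignments.score <= 0:
        return False
    best = alignments[0]
    counts = best.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    if ncols < min_overlap_nt:
        return False
    identity = 100.0 * counts.identities / ncols
    return identity >= min_identity_pct


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _kmer_candidates(seqs: list[str], k: int = 16) -> set[tuple[int, int]]:
    """Index k-mers to propose pairs that could satisfy a long exact-ish overlap.

    Every position is indexed (a sampled index can miss shifted overlaps);
    homopolymer k-mers are skipped — poly-A tails alone can never supply a
    qualifying 100-nt overlap but would link everything to everything.
    """
    index: dict[str, set[int]] = defaultdict(set)
    for i, s in enumerate(seqs):
        for j in range(0, max(0, len(s) - k + 1)):
            kmer = s[j:j + k]
            if len(set(kmer)) > 1:
                index[kmer].add(i)
    pairs: set[tuple[int, int]] = set()
    for members in index.values():
        if len(members) < 2:
            continue
        ms = sorted(members)
        for x in range(len(ms)):
            for y in range(x + 1, len(ms)):
                pairs.add((ms[x], ms[y]))
    return pairs


def cluster_ests(ests: list[ESTRecord],
                 min_overlap_nt: int = DEFAULT_MIN_OVERLAP_NT,
                 min_identity_pct: float = DEFAULT_MIN_IDENTITY_PCT,
                 category: str = "all",
                 use_kmer_prefilter: bool = True) -> ClusterSet:
    """Single-linkage clustering of ESTs under the overlap relation.

    Identical sequences are deduplicated before alignment.  With the k-mer
    prefilter on (default), only pairs sharing a 16-mer are aligned; at the
    default thresholds (100 nt overlap at >=95% identity) any qualifying
    pair must share many exact 16-mers, so the prefilter does not change
    the partition.  Cluster ids are deterministic: each cluster is named
    after its lexicographically smallest member id.
    """
    if not ests:
        return ClusterSet(category=category, clusters=[], bins=_empty_bins())
    order = sorted(range(len(ests)), key=lambda i: ests[i].id)
    ests = [ests[i] for i in order]

    # collapse exact duplicates
    seq_to_first: dict[str, int] = {}
    dup_of: list[int] = []
    uniq_seqs: list[str] = []
    for i, est in enumerate(ests):
        j = seq_to_first.get(est.seq)
        if j is None:
            seq_to_first[est.seq] = len(uniq_seqs)
            dup_of.append(len(uniq_seqs))
            uniq_seqs.append(est.seq)
        else:
            dup_of.append(j)

    uf = _UnionFind(len(uniq_seqs))
    aligner = _dna_aligner()
    if use_kmer_prefilter:
        pairs = _kmer_candidates(uniq_seqs)
    else:
        pairs = {(i, j) for i in range(len(uniq_seqs))
                 for j in range(i + 1, len(uniq_seqs))}
    for i, j in sorted(pairs):
        if uf.find(i) == uf.find(j):
            continue
        if ests_overlap(uniq_seqs[i], uniq_seqs[j], min_overlap_nt,
                        min_identity_pct, _aligner=aligner):
            uf.union(i, j)

    groups: dict[int, list[int]] = defaultdict(list)
    for i, est in enumerate(ests):
        groups[uf.find(dup_of[i])].append(i)

    clusters = []
    for root in sorted(groups):
        members = groups[root]
        member_ids = [ests[i].id for i in members]
        rep = max((ests[i].seq for i in members), key=len)
        genes = {trim_polya(ests[i].seq) for i in members}
        clusters.append(Contig(id=f"cl_{min(member_ids)}",
                               member_est_ids=member_ids,
                               consensus_nt=rep,
                               unique_gene_seqs=genes))
    clusters.sort(key=lambda c: c.id)
    cs = ClusterSet(category=category, clusters=clusters)
    cs.bins = bin_table(cs)
    return cs


def count_unique(contig: Contig,
                 proteins_by_est: dict[str, str] | None = None) -> tuple[int, int]:
    """(unique genes, unique proteins) of a contig.

    Genes are distinct member nucleotide strings after poly-A trimming;
    proteins are distinct predicted precursor strings supplied per EST
    (ESTs without a prediction do not contribute a protein).
    """
    n_genes = len(contig.unique_gene_seqs)
    if proteins_by_est is not None:
        prots = {proteins_by_est[eid] for eid in contig.member_est_ids
                 if proteins_by_est.get(eid)}
        contig.unique_protein_seqs = prots
    return n_genes, len(contig.unique_protein_seqs)


def _empty_bins() -> dict[str, dict[str, int]]:
    return {b: {"n_contigs": 0, "n_ests": 0,
                "n_unique_genes": 0, "n_unique_proteins": 0}
            for b in SIZE_BINS}


def bin_table(cs: ClusterSet,
              proteins_by_est: dict[str, str] | None = None) -> dict[str, dict[str, int]]:
    """Per-size-bin contig/EST/unique-gene/unique-protein counts."""
    bins = _empty_bins()
    for contig in cs.clusters:
        g, p = count_unique(contig, proteins_by_est)
        b = bins[size_bin(contig.size)]
        b["n_contigs"] += 1
        b["n_ests"] += contig.size
        b["n_unique_genes"] += g
        b["n_unique_proteins"] += p
    return bins


def summarize_categories(annotations: list) -> dict[str, dict[str, float]]:
    """Per-category counts and percentages (2 decimals) over all annotations.

    Accepts Annotation objects or plain (category) strings.  An empty input
    yields an empty summary rather than dividing by zero.
    """
    counts: dict[str, int] = defaultdict(int)
    for ann in annotations:
        cat = ann if isinstance(ann, str) else ann.category
        counts[cat] += 1
    total = sum(counts.values())
    summary: dict[str, dict[str, float]] = {}
    for cat in sorted(counts):
        pct = round(100.0 * counts[cat] / total, 2) if total else 0.0
        summary[cat] = {"count": counts[cat], "pct": pct}
    return summary
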