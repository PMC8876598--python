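"""Six-frame translation and homology-based EST classification.

Each EST is translated in all six reading frames; open reading frames
(Met-to-stop, or open-ended at a sequence terminus to support fragments)
are aligned locally (Smith-Waterman) against a curated reference protein
set containing toxin and cellular exemplars.  The best hit over all
ORF x reference pairs annotates the EST, provided its e-value passes the
cutoff (default 1e-5); otherwise the EST is a no-match.

E-values follow the Karlin-Altschul form E = K*m*n*exp(-lambda*S) with the
standard gapped BLOSUM62 (open 11 / extend 1) parameters lambda = 0.267,
K = 0.041, so the familiar 1e-5 cutoff keeps its usual meaning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .seqio import ESTRecord, ReferenceEntry

# Gapped Karlin-Altschul parameters for BLOSUM62, gap open 11 / extend 1.
KA_LAMBDA = 0.267
KA_K = 0.041

DEFAULT_EVALUE_CUTOFF = 1e-5
DEFAULT_MIN_ORF_AA = 20

STOP = "*"


@dataclass
class Orf:
    """One candidate open reading frame from a six-frame scan."""

    frame: int            # 1..3 forward, -1..-3 reverse
    protein: str
    has_start: bool       # begins at an in-frame ATG
    has_stop: bool        # ends at an in-frame stop codon
    aa_start: int         # 0-based index within the frame's translation


@dataclass
class Annotation:
    est_id: str
    category: str                      # toxin_like | cellular | no_match
    best_hit_id: str | None = None
    score: float = 0.0
    evalue: float = math.inf
    identity_pct: float = 0.0
    frame: int = 0
    orf_protein: str = ""
    secondary_hit: bool = False        # another ORF also passed the cutoff
    notes: list[str] = field(default_factory=list)


def _frame_translations(seq: str) -> list[tuple[int, str]]:
    """Translate all six frames, returning (frame, aa-string with '*' stops)."""
    out = []
    fwd = Seq(seq)
    rev = fwd.reverse_complement()
    for off in range(3):
        for frame, s in ((off + 1, fwd), (-(off + 1), rev)):
            sub = s[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            out.append((frame, str(sub.translate())))
    return out


def translate_orfs(est: ESTRecord | str, min_orf_aa: int = DEFAULT_MIN_ORF_AA) -> list[Orf]:
    """Scan all six frames for ORFs.

    Within each frame the translation is split at stop codons.  A segment
    contributes (a) its Met-to-stop ORF when it contains a Met, and (b) the
    whole segment when it is open at the 5' end of the frame (no upstream
    stop), so that 5'-truncated fragments still yield a searchable peptide.
    Segments at the 3' end without a stop codon are open-ended (has_stop
    False).  ORFs containing X (from an N base) are dropped rather than
    fabricating residues.
    """
    seq = est.seq if isinstance(est, ESTRecord) else est.upper()
    orfs: list[Orf] = []
    for frame, aa in _frame_translations(seq):
        pos = 0
        first_segment = True
        while pos <= len(aa):
            stop_idx = aa.find(STOP, pos)
            if stop_idx == -1:
                segment, has_stop, nxt = aa[pos:], False, len(aa) + 1
            else:
                segment, has_stop, nxt = aa[pos:stop_idx], True, stop_idx + 1
            candidates: list[tuple[str, bool, int]] = []
            m = segment.find("M")
            if first_segment and segment and (m == -1 or m > 10):
                # open at the frame's 5' end and no credible start codon
                # nearby: keep the whole segment for fragment support
                candidates.append((segment, False, pos))
            if m != -1:
                candidates.append((segment[m:], True, pos + m))
            for prot, has_start, aa_start in candidates:
                if len(prot) >= min_orf_aa and "X" not in prot:
                    orfs.append(Orf(frame=frame, protein=prot,
                                    has_start=has_start, has_stop=has_stop,
                                    aa_start=aa_start))
            pos = nxt
            first_segment = False
    return orfs


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float, mode: str) -> PairwiseAligner:
    try:
        m = substitution_matrices.load(matrix)
    except Exception as exc:
        raise ValueError(f"unknown substitution matrix {matrix!r}") from exc
    aln = PairwiseAligner()
    aln.substitution_matrix = m
    # BLAST-style affine cost: a gap of length k costs open + k*extend
    aln.open_gap_score = -(gap_open + gap_extend)
    aln.extend_gap_score = -gap_extend
    aln.mode = mode
    return aln


def local_align(query: str, subject: str, matrix: str = "BLOSUM62",
                gap_open: float = 11.0, gap_extend: float = 1.0
                ) -> tuple[float, float, int]:
    """Optimal Smith-Waterman local alignment.

    Returns (score, identity_pct over aligned columns, aligned span in
    columns).  Raises ValueError for an unknown matrix name or empty input.
    """
    if not query or not subject:
        raise ValueError("local_align requires non-empty sequences")
    aligner = _aligner(matrix, gap_open, gap_extend, "local")
    alignments = aligner.align(query, subject)
    score = alignments.score
    if score <= 0:
        return 0.0, 0.0, 0
    best = alignments[0]
    counts = best.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / ncols if ncols else 0.0
    return float(score), identity, int(ncols)


def evalue_from_score(score: float, query_len: int, db_residues: int,
                      ka_lambda: float = KA_LAMBDA, ka_k: float = KA_K) -> float:
    """Karlin-Altschul e-value for a local alignment score."""
    if score <= 0:
        return math.inf
    return ka_k * query_len * db_residues * math.exp(-ka_lambda * score)


def calibrate_karlin_altschul(rng, n_samples: int = 150, m: int = 120,
                              n: int = 120, matrix: str = "BLOSUM62",
                              gap_open: float = 11.0, gap_extend: float = 1.0
                              ) -> tuple[float, float]:
    """Fit (lambda, K) from a shuffled-sequence score null.

    Smith-Waterman scores of random sequence pairs follow a Gumbel law
    P(S > x) ~ K*m*n*exp(-lambda*x); the fit uses the method of moments
    (lambda = pi / (sqrt(6) sigma), mode mu = mean - gamma/lambda,
    K = exp(lambda*mu) / (m*n)).  The shipped defaults KA_LAMBDA / KA_K
    are the standard gapped-BLOSUM62 values; this fit exists to verify
    they are appropriate for this aligner configuration.
    """
    import numpy as np
    aas = "ACDEFGHIKLMNPQRSTVWY"
    aligner = _aligner(matrix, gap_open, gap_extend, "local")
    scores = []
    for _ in range(n_samples):
        a = "".join(aas[i] for i in rng.integers(0, 20, m))
        b = "".join(aas[i] for i in rng.integers(0, 20, n))
        scores.append(float(aligner.score(a, b)))
    scores = np.asarray(scores)
    lam = math.pi / (math.sqrt(6) * scores.std())
    mu = scores.mean() - 0.5772156649 / lam
    k = math.exp(lam * mu) / (m * n)
    return lam, k


def classify_est(est: ESTRecord, refs: list[ReferenceEntry],
                 evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
                 min_orf_aa: int = DEFAULT_MIN_ORF_AA,
                 matrix: str = "BLOSUM62",
                 gap_open: float = 11.0, gap_extend: float = 1.0) -> Annotation:
    """Annotate one EST by its best reference hit over all ORFs.

    Category is inherited from the best hit's reference category
    (toxin -> toxin_like, cellular -> cellular); sub-cutoff ESTs are
    no_match.  Score ties break by higher identity, then reference id.
    """
    if not refs:
        raise ValueError("reference set must be non-empty")
    db_residues = sum(len(r.seq) for r in refs)
    aligner = _aligner(matrix, gap_open, gap_extend, "local")
    orfs = translate_orfs(est, min_orf_aa=min_orf_aa)
    # Score-only pass first (fast); traceback only for the top scorers.
    hits: list[tuple[float, float, int, ReferenceEntry]] = []
    passing_orfs: set[int] = set()
    for orf_idx, orf in enumerate(orfs):
        for ref in refs:
            score = float(aligner.score(orf.protein, ref.seq))
            ev = evalue_from_score(score, len(orf.protein), db_residues)
            if ev > evalue_cutoff:
                continue
            passing_orfs.add(orf_idx)
            hits.append((score, ev, orf_idx, ref))
    if not hits:
        est.category = "no_match"
        # keep the most plausible translation so non-matched ESTs still
        # contribute to non-redundant protein counts
        longest = max(orfs, key=lambda o: (len(o.protein), o.frame),
                      default=None)
        return Annotation(est_id=est.id, category="no_match",
                          frame=longest.frame if longest else 0,
                          orf_protein=longest.protein if longest else "")
    best_score = max(h[0] for h in hits)
    contenders = []
    for score, ev, orf_idx, ref in hits:
        if score == best_score:
            orf = orfs[orf_idx]
            _, identity, _ = local_align(orf.protein, ref.seq, matrix,
                                         gap_open, gap_extend)
            contenders.append((identity, ref.id, score, ev, orf))
    # highest identity wins; then the longest ORF (a fragment's open-ended
    # ORF covers the whole remnant); then the smaller reference id
    contenders.sort(key=lambda c: (-c[0], -len(c[4].protein), c[1]))
    identity, ref_id, score, ev, orf = contenders[0]
    ref = next(r for r in refs if r.id == ref_id)
    ann = Annotation(
        est_id=est.id,
        category="toxin_like" if ref.category == "toxin" else "cellular",
        best_hit_id=ref.id, score=score, evalue=ev,
        identity_pct=identity, frame=orf.frame, orf_protein=orf.protein)
    if len(passing_orfs) > 1:
        ann.secondary_hit = True
        ann.notes.append("secondary_orf_hit")
    est.category = ann.category
    return ann


def name_toxin(clone_number: int, is_partial: bool = False,
               from_transcriptome: bool = False, prefix: str = "HptTx") -> str:
    """Build a toxin name: ``<prefix>-<n>`` plus ``-P`` / ``-T`` suffixes.

    ``-P`` marks a partial sequence and ``-T`` a transcriptome-derived one,
    in that order when both apply.
    """
    if clone_number < 0:
        raise ValueError("clone_number must be >= 0")
    name = f"{prefix}-{clone_number}"
    if is_partial:
        name += "-P"
    if from_transcriptome:
        name += "-T"
    return name
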