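"""Toxin precursor segmentation: signal peptide, propeptide, mature peptide.

Spider toxin precursors follow a canonical architecture: an N-terminal
secretion signal peptide, an optional acidic propeptide removed at a
Processing Quadruplet Motif (PQM: an arginine preceded within three
residues by at least one acidic residue), and a cysteine-scaffolded
mature peptide.  A C-terminal glycine (optionally followed by K/R
processing residues) marks enzymatic amidation of the preceding residue.

The signal cleavage site is predicted by a lightweight signal-anchor
heuristic (hydrophobic h-region plus small residues at the -3/-1
positions of the cut, the classic (-3,-1) rule); externally computed
cleavage sites (e.g. a SignalP result table) can be imported and take
precedence when supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

# Kyte-Doolittle hydropathy
KD = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

SMALL_RESIDUES = frozenset("AGSCT")  # tolerated at the -3/-1 cut positions
ACIDIC = frozenset("ED")

DEFAULT_MAX_PRO_LEN = 40
SIGNAL_MIN_CUT = 15
SIGNAL_MAX_CUT = 35
SIGNAL_SCORE_THRESHOLD = 1.0
MIN_CORE_HYDROPATHY = 1.0  # mean Kyte-Doolittle floor for the h-region window


@dataclass
class ToxinPrecursor:
    """A segmented toxin precursor.

    ``signal``, ``propeptide`` and ``mature`` are half-open (start, end)
    index pairs into ``full_seq``; ``propeptide`` is None when no PQM cut
    exists.  For an amidated peptide the glycine signal (and any trailing
    K/R) sits between ``mature[1]`` and the end of ``full_seq``.
    """

    name: str
    full_seq: str
    est_id: str = ""
    signal: tuple[int, int] | None = None
    propeptide: tuple[int, int] | None = None
    mature: tuple[int, int] = (0, 0)
    amidated: bool = False
    completeness: str = "full_length"
    notes: list[str] = field(default_factory=list)

    @property
    def signal_seq(self) -> str:
        return self.full_seq[slice(*self.signal)] if self.signal else ""

    @property
    def propeptide_seq(self) -> str:
        return self.full_seq[slice(*self.propeptide)] if self.propeptide else ""

    @property
    def mature_seq(self) -> str:
        return self.full_seq[slice(*self.mature)]


@dataclass
class OrfContext:
    """Start/stop evidence for completeness classification."""

    has_start: bool
    has_stop: bool
    source: str = "library"  # library | transcriptome
    has_signal: bool = True
    mature_len: int | None = None
    reference_mature_len: float | None = None  # e.g. family median
    internal_stop: bool = False


def predict_signal_peptide(precursor_seq: str,
                           min_cut: int = SIGNAL_MIN_CUT,
                           max_cut: int = SIGNAL_MAX_CUT,
                           threshold: float = SIGNAL_SCORE_THRESHOLD) -> int | None:
    """Predict the signal peptide cleavage position (residues before the cut).

    Candidate cut positions ``p`` in [min_cut, max_cut] are scored as the
    mean Kyte-Doolittle hydropathy of the putative h-region window
    (residues p-9..p-4, 0-based) plus bonuses for small residues at the
    -1 (+1.5) and -3 (+1.0) positions; windows whose mean hydropathy falls
    below ``MIN_CORE_HYDROPATHY`` are disqualified outright.  The
    best-scoring position above ``threshold`` wins, ties to the smallest
    p.  Returns None for sequences shorter than min_cut or with no
    qualifying position (e.g. no hydrophobic core).
    """
    seq = precursor_seq.upper()
    if len(seq) < min_cut:
        return None
    best_p, best_score = None, -1e9
    for p in range(min_cut, min(max_cut, len(seq) - 1) + 1):
        window = seq[max(0, p - 9): p - 3]
        if not window:
            continue
        hydro = sum(KD.get(c, 0.0) for c in window) / len(window)
        if hydro < MIN_CORE_HYDROPATHY:
            continue  # a signal peptide requires a hydrophobic h-region
        score = hydro
        if seq[p - 1] in SMALL_RESIDUES:
            score += 1.5
        if seq[p - 3] in SMALL_RESIDUES:
            score += 1.0
        if score > best_score:
            best_score, best_p = score, p
    if best_p is None or best_score < threshold:
        return None
    return best_p


def load_signal_cuts(path: str | Path) -> dict[str, int]:
    """Import externally computed signal cleavage sites (TSV: name <tab> cut).

    The cut value is the signal peptide length (number of residues before
    the cleavage site), as reported by signal-peptide predictors.
    """
    cuts: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("name"):
                continue
            name, cut = line.split("\t")[:2]
            cuts[name] = int(cut)
    return cuts


def trim_signal_remnant(seq: str, max_len: int = 12,
                        min_mean_kd: float = 0.5) -> int | None:
    """Detect a residual (5'-truncated) signal peptide prefix.

    A fragment that lost its start codon may still carry the tail of the
    signal peptide: a hydrophobic-leaning prefix ending in a small
    residue.  Returns the longest prefix length p <= max_len, before the
    first cysteine, with a small residue at p-1 and mean Kyte-Doolittle
    hydropathy >= ``min_mean_kd``; None when no such prefix exists.
    """
    first_c = seq.find("C")
    limit = min(max_len, len(seq) - 10,
                first_c if first_c != -1 else len(seq))
    best = None
    total = 0.0
    for p in range(1, max(0, limit) + 1):
        total += KD.get(seq[p - 1], 0.0)
        if seq[p - 1] in SMALL_RESIDUES and total / p >= min_mean_kd:
            best = p
    return best


def find_pqm_cut(downstream_seq: str,
                 max_pro_len: int = DEFAULT_MAX_PRO_LEN,
                 acidic: frozenset[str] | str = ACIDIC) -> int | None:
    """Locate the propeptide/mature cut by the Processing Quadruplet Motif.

    Scans the region after the signal cut for arginines (P1) preceded by at
    least one acidic residue among the three preceding positions (P2-P4).
    The latest qualifying R that lies before the first cysteine and within
    ``max_pro_len`` wins; the cut falls immediately after it.  None means
    no propeptide: the mature peptide starts at the signal cut.
    """
    acidic = frozenset(acidic)
    seq = downstream_seq.upper()
    first_cys = seq.find("C")
    limit = min(max_pro_len, len(seq))
    if first_cys != -1:
        limit = min(limit, first_cys)
    cut = None
    for i in range(limit):
        if seq[i] != "R":
            continue
        p2_p4 = seq[max(0, i - 3): i]
        if any(c in acidic for c in p2_p4):
            cut = i + 1
    return cut


def detect_amidation(mature_plus_tail: str) -> tuple[bool, str]:
    """Detect and strip a C-terminal amidation signal (G, GK, GR or GKR).

    The glycine donates the amide to the preceding residue; trailing K/R
    after the glycine are basic processing residues excised with it.
    Returns (amidated, trimmed mature sequence).
    """
    seq = mature_plus_tail
    for tail in ("GKR", "GK", "GR", "G"):
        if seq.endswith(tail) and len(seq) > len(tail):
            return True, seq[: -len(tail)]
    return False, seq


def flag_partial(ctx: OrfContext, readthrough_margin: int = 6) -> tuple[str, list[str]]:
    """Classify precursor completeness and collect anomaly notes.

    * full_length: Met start and stop codon observed.
    * n_truncated: missing start (5' fragment) but a signal remnant or more.
    * mature_only: missing start and no recognizable signal peptide.
    * c_truncated: no stop codon (3' fragment).

    When a reference mature length (e.g. the family median) is supplied,
    a mature peptide running ``readthrough_margin`` residues past it on a
    stop-terminated ORF is flagged ``stop_readthrough`` (stop-codon loss,
    e.g. UGA->CGA); an internal stop shortening it is ``premature_stop``.
    """
    notes: list[str] = []
    if ctx.has_start and ctx.has_stop:
        completeness = "full_length"
    elif not ctx.has_start:
        completeness = "n_truncated" if ctx.has_signal else "mature_only"
    else:
        completeness = "c_truncated"
    if ctx.internal_stop:
        notes.append("premature_stop")
    if (ctx.reference_mature_len is not None and ctx.mature_len is not None
            and ctx.has_stop
            and ctx.mature_len >= ctx.reference_mature_len + readthrough_margin):
        notes.append("stop_readthrough")
    return completeness, notes


def segment_precursor(name: str, full_seq: str,
                      ctx: OrfContext | None = None,
                      signal_cut: int | None = None,
                      max_pro_len: int = DEFAULT_MAX_PRO_LEN,
                      acidic: frozenset[str] | str = ACIDIC) -> ToxinPrecursor:
    """Segment a translated precursor into signal/propeptide/mature.

    ``signal_cut`` overrides the heuristic (external predictor import).
    For ORFs lacking a start codon the signal is taken as absent and the
    whole sequence is treated as propeptide+mature context.
    """
    seq = full_seq.upper().rstrip("*")
    prec = ToxinPrecursor(name=name, full_seq=seq)
    has_start = ctx.has_start if ctx else seq.startswith("M")
    has_stop = ctx.has_stop if ctx else True

    if signal_cut is None and has_start:
        signal_cut = predict_signal_peptide(seq)
    elif signal_cut is None and not has_start:
        # the fragment may retain a nearly complete signal peptide (lost
        # start codon) or just its hydrophobic tail
        signal_cut = predict_signal_peptide(seq) or trim_signal_remnant(seq)
        if signal_cut:
            prec.notes.append("signal_remnant")
    if signal_cut:
        prec.signal = (0, signal_cut)
        downstream_start = signal_cut
    else:
        downstream_start = 0

    downstream = seq[downstream_start:]
    pqm = find_pqm_cut(downstream, max_pro_len=max_pro_len, acidic=acidic)
    if pqm:
        prec.propeptide = (downstream_start, downstream_start + pqm)
        mature_start = downstream_start + pqm
    else:
        mature_start = downstream_start

    # an amidation signal is only callable when the C-terminus is complete
    if has_stop:
        amidated, trimmed = detect_amidation(seq[mature_start:])
    else:
        amidated, trimmed = False, seq[mature_start:]
    prec.amidated = amidated
    prec.mature = (mature_start, mature_start + len(trimmed))

    if ctx is None:
        ctx = OrfContext(has_start=has_start, has_stop=True,
                         has_signal=prec.signal is not None)
    else:
        ctx.has_signal = prec.signal is not None
    ctx.mature_len = len(trimmed)
    prec.completeness, flags = flag_partial(ctx)
    prec.notes.extend(flags)
    return prec
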