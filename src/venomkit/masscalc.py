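"""Theoretical peptide masses and MALDI-TOF peak matching.

Mature toxin masses are computed on the average (default, matching
linear-mode MALDI) or monoisotopic scale, with two corrections applied to
the linear free peptide:

* each disulfide bond removes two hydrogens (-2.01588 Da average);
* C-terminal amidation replaces the terminal -OH by -NH2 (-0.98476 Da
  average).

Three disulfides plus amidation therefore lighten a peptide by about
7 Da.  Observed m/z peaks are interpreted both as singly protonated ions
(M+H) and as doubly protonated ions read at half mass ((M+2H)/2), and
matched to candidate masses within a configurable tolerance (default
2.0 Da, linear-mode accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as pmass

from .seqio import PeakList

PROTON_MASS = 1.00728           # Da, for charge arithmetic
H_AVG = 1.00794                 # average hydrogen
H_MONO = 1.0078250319
AMIDATION_DELTA_AVG = -0.98476  # OH -> NH2
AMIDATION_DELTA_MONO = -0.9840155848

DEFAULT_TOLERANCE_DA = 2.0
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class PeptideMass:
    sequence: str
    n_disulfides: int = 0
    amidated: bool = False
    name: str = ""
    mass_avg: float = field(init=False)
    mass_mono: float = field(init=False)

    def __post_init__(self) -> None:
        n_cys = self.sequence.upper().count("C")
        if 2 * self.n_disulfides > n_cys:
            raise ValueError(
                f"{self.name or self.sequence[:12]}: {self.n_disulfides} disulfides "
                f"need {2 * self.n_disulfides} cysteines, found {n_cys}")
        self.mass_avg = peptide_mass(self.sequence, self.n_disulfides,
                                     self.amidated, scale="average")
        self.mass_mono = peptide_mass(self.sequence, self.n_disulfides,
                                      self.amidated, scale="monoisotopic")


@dataclass
class MassMatch:
    peak_mz: float
    candidate: str
    charge_interpretation: str  # "M+H" | "M+2H_over_2"
    theoretical_mass: float
    observed_mass: float
    delta_da: float
    within_tolerance: bool


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty peptide sequence")
    bad = set(seq) - STANDARD_AA
    if bad:
        raise ValueError(f"nonstandard residues {sorted(bad)} in {sequence[:20]!r}")
    return seq


def modification_delta(n_disulfides: int, amidated: bool,
                       scale: str = "average") -> float:
    """Total (negative) mass correction for disulfides and amidation."""
    if n_disulfides < 0:
        raise ValueError("n_disulfides must be >= 0")
    h = H_AVG if scale == "average" else H_MONO
    amide = AMIDATION_DELTA_AVG if scale == "average" else AMIDATION_DELTA_MONO
    delta = -2.0 * h * n_disulfides
    if amidated:
        delta += amide
    return delta


def peptide_mass(sequence: str, n_disulfides: int = 0, amidated: bool = False,
                 scale: str = "average") -> float:
    """Theoretical mass (Da) of a modified peptide.

    Residue masses plus one water, corrected for disulfide hydrogen loss
    and C-terminal amidation.
    """
    if scale not in ("average", "monoisotopic"):
        raise ValueError(f"scale must be 'average' or 'monoisotopic', got {scale!r}")
    seq = _check_sequence(sequence)
    linear = pmass.calculate_mass(sequence=seq, average=(scale == "average"))
    return linear + modification_delta(n_disulfides, amidated, scale)


def default_disulfide_count(n_cys: int, template_pairs: int | None = None) -> int:
    """floor(n_cys/2), capped by the assigned template's pair count if known."""
    n = n_cys // 2
    if template_pairs is not None:
        n = min(n, template_pairs)
    return n


def match_peaks(peaks: PeakList, candidates: list[PeptideMass],
                tolerance_da: float = DEFAULT_TOLERANCE_DA,
                scale: str = "average") -> list[MassMatch]:
    """Match observed m/z peaks to candidate masses.

    Each peak is tested under both charge interpretations —
    M = mz - 1.00728 (M+H) and M = 2*mz - 2*1.00728 ((M+2H)/2) — against
    every candidate; all within-tolerance pairings are returned, sorted
    by |delta| ascending.
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance_da must be positive")
    matches: list[MassMatch] = []
    for mz, _inten in peaks.peaks:
        interps = (("M+H", mz - PROTON_MASS),
                   ("M+2H_over_2", 2.0 * mz - 2.0 * PROTON_MASS))
        for interp, observed_m in interps:
            for cand in candidates:
                theo = cand.mass_avg if scale == "average" else cand.mass_mono
                delta = observed_m - theo
                if abs(delta) <= tolerance_da:
                    matches.append(MassMatch(
                        peak_mz=mz, candidate=cand.name or cand.sequence,
                        charge_interpretation=interp,
                        theoretical_mass=theo, observed_mass=observed_m,
                        delta_da=delta, within_tolerance=True))
    matches.sort(key=lambda m: (abs(m.delta_da), m.peak_mz, m.candidate))
    return matches


def identify_by_nterm(edman_prefix: str, db: list,
                      observed_mw: float,
                      tolerance_da: float = DEFAULT_TOLERANCE_DA,
                      scale: str = "average") -> list[dict]:
    """Identify a purified peptide from its Edman N-terminal prefix.

    Searches precursors whose mature peptide starts with the prefix
    (exact; if nothing matches, up to one mismatch), computes each
    candidate's theoretical modified mass (disulfides = floor(n_cys/2),
    amidation from the precursor call) and checks it against the observed
    molecular weight.  Results are ranked exact-match first, then by
    |mass delta|.
    """
    prefix = edman_prefix.upper()
    if len(prefix) < 5:
        raise ValueError("Edman prefix must be at least 5 residues")

    def mismatches(s: str) -> int:
        return sum(1 for a, b in zip(prefix, s) if a != b)

    hits: list[dict] = []
    for prec in db:
        mature = prec.mature_seq
        if len(mature) < len(prefix):
            continue
        mm = mismatches(mature[: len(prefix)])
        if mm > 1:
            continue
        n_ss = default_disulfide_count(mature.count("C"))
        theo = peptide_mass(mature, n_ss, prec.amidated, scale=scale)
        delta = observed_mw - theo
        hits.append({
            "name": prec.name, "mature": mature, "prefix_mismatches": mm,
            "n_disulfides": n_ss, "amidated": prec.amidated,
            "theoretical_mw": theo, "observed_mw": observed_mw,
            "delta_da": delta, "mw_check_pass": abs(delta) <= tolerance_da,
        })
    exact = [h for h in hits if h["prefix_mismatches"] == 0]
    pool = exact if exact else hits
    pool.sort(key=lambda h: (h["prefix_mismatches"], abs(h["delta_da"]), h["name"]))
    return pool


def mw_distribution(masses: list[float], bin_width: float = 500.0,
                    window: tuple[float, float] = (1000.0, 10000.0)
                    ) -> dict[str, int]:
    """Histogram of masses over the MALDI acquisition window (1-10 kDa)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = window
    nbins = int((hi - lo) // bin_width) + (1 if (hi - lo) % bin_width else 0)
    labels = [f"{lo + i * bin_width:g}-{min(lo + (i + 1) * bin_width, hi):g}"
              for i in range(nbins)]
    hist = {lab: 0 for lab in labels}
    for m in masses:
        if m < lo or m > hi:
            continue
        k = min(int((m - lo) // bin_width), nbins - 1)
        hist[labels[k]] += 1
    return hist
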