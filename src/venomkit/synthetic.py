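"""Synthetic venom-gland cDNA library with full ground truth.

The generator emulates the composition of a spider venom-gland cDNA
library at the scale and proportions typical of such studies: roughly
half the transcripts encode secreted toxin precursors (signal peptide,
optional acidic propeptide ending in a PQM arginine, cysteine-scaffolded
mature peptide, optional amidation tail, stop codon, poly-A), a quarter
encode abundant cellular proteins, and the remainder match nothing.

Realistic nuisance processes are planted with known labels: copy-number
skew (Zipf-like, so most toxin ESTs fall in multi-member contigs),
synonymous and non-synonymous point mutations, loss of a conserved
cysteine, stop-codon gain (UAC->UAG) and stop-codon readthrough
(UGA->CGA), and 5'/3' mRNA fragmentation.  Every emitted transcript is
described by a manifest row whose fields are re-derivable from the
sequence itself, so pipeline outputs can be scored against exact truth.

Family seed scaffolds are sampled to be mutually dissimilar (<20%
pairwise mature identity), mirroring toxin families that descend from
separate ancestors rather than one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import masscalc
from .framework import extract_framework
from .seqio import ESTRecord, PeakList, ReferenceEntry

# codon table (standard code), synonymous sets per amino acid
_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}
_STOPS = ("TGA", "TAA", "TAG")
_CODON_TO_AA = {c: aa for aa, cs in _CODONS.items() for c in cs}
for _s in _STOPS:
    _CODON_TO_AA[_s] = "*"

# consensus cysteine scaffolds of thirteen toxin families (A-M) as
# reported for huntsman-spider venom glands; some families legitimately
# share a framework and are separated by homology.
DEFAULT_FAMILY_SCAFFOLDS: tuple[str, ...] = (
    "C1-C2-C3C4-C5-C6-C7-C8-C9-C10",   # MIT1-like
    "C1-C2-C3C4-C5-C6C7-C8-C9-C10",
    "C1-C2-C3C4-C5-C6",                # ICK
    "C1-C2-C3-C4-C5-C6-C7-C8-C9-C10",
    "C1-C2-C3C4-C5-C6-C7-C8",
    "C1-C2-C3-C4-C5-C6C7-C8",
    "C1-C2-C3-C4-C5-C6C7-C8",
    "C1-C2-C3-C4",
    "C1-C2",
    "C1-C2-C3C4-C5-C6-C7-C8",
    "C1-C2-C3C4-C5-C6",
    "C1-C2-C3C4-C5-C6",
    "C1-C2-C3C4-C5-C6",
)

_H_RESIDUES = "LIVFM"          # hydrophobic signal core
_C_RESIDUES = "SGTA"           # small residues at the signal cut
_N_RESIDUES = "KRNQ"           # short positively-charged n-region
_PRO_RESIDUES = "EDANSQGT"     # acidic-leaning propeptide (no R, no C)
_LOOP_RESIDUES = "ADEFGHIKLMNPQSTVWY"   # inter-cysteine loops (no C, no R)
_LOOP_RESIDUES_RK = _LOOP_RESIDUES + "R"  # allowed after the first cysteine
_TERMINAL_RESIDUES = "LIFWYVDENQM"      # mature C-terminus (no G/K/R)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic library."""

    seed: int = 0
    n_toxin_seeds: int = 13
    n_transcripts: int = 1000
    # toxin-like / cellular / no-match proportions
    category_proportions: tuple[float, float, float] = (0.5358, 0.2573, 0.2069)
    copy_zipf_exponent: float = 1.2
    point_mutation_rate: float = 0.002     # per nt per transcript copy
    cys_loss_rate: float = 0.01            # per toxin transcript
    stop_gain_rate: float = 0.005
    stop_readthrough_rate: float = 0.005
    fragmentation_prob: float = 0.10
    transcriptome_fraction: float = 0.05   # toxin transcripts tagged as RNA-seq derived
    family_scaffolds: tuple[str, ...] = DEFAULT_FAMILY_SCAFFOLDS
    n_cellular_exemplars: int = 12
    n_fractions: int = 6
    noise_peaks_per_fraction: int = 3

    def __post_init__(self) -> None:
        if abs(sum(self.category_proportions) - 1.0) > 1e-9:
            raise ValueError("category_proportions must sum to 1")
        rates = (self.point_mutation_rate, self.cys_loss_rate,
                 self.stop_gain_rate, self.stop_readthrough_rate,
                 self.fragmentation_prob, self.transcriptome_fraction)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.n_toxin_seeds > len(self.family_scaffolds):
            raise ValueError("need at least one scaffold per toxin seed")


@dataclass
class ManifestRow:
    id: str
    category: str                      # toxin_like | cellular | no_match
    source: str = "library"
    family: int | None = None
    gene: str | None = None
    protein: str = ""                  # encoded precursor (post-mutation truth)
    signal_len: int = 0
    pro_len: int = 0
    mature_seq: str = ""
    amidation: str = "none"            # none | G | GK | GR
    framework_notation: str = ""
    mature_mass_avg: float = 0.0
    completeness: str = "full_length"
    anomalies: list[str] = field(default_factory=list)
    fragmented: str = "none"           # none | 5p | 3p


@dataclass
class LibraryBundle:
    records: list[ESTRecord]
    manifest: dict[str, ManifestRow]
    references: list[ReferenceEntry]
    peaklists: list[PeakList]
    config: GeneratorConfig


def _rt(rng: np.random.Generator, protein: str) -> str:
    """Reverse-translate with codons drawn uniformly over synonymous sets."""
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein)


def _utr(rng: np.random.Generator, lo: int, hi: int) -> str:
    """Random untranslated sequence with no ATG (no spurious start codons)."""
    s = _choice(rng, "ACGT", int(rng.integers(lo, hi)))
    while "ATG" in s:
        s = s.replace("ATG", "ACG")
    return s


def _choice(rng: np.random.Generator, letters: str, n: int) -> str:
    return "".join(letters[i] for i in rng.integers(0, len(letters), n))


def _translate(cds: str) -> str:
    aas = []
    for i in range(0, len(cds) - 2, 3):
        aa = _CODON_TO_AA.get(cds[i:i + 3])
        if aa is None or aa == "*":
            break
        aas.append(aa)
    return "".join(aas)


def _scaffold_gaps(notation: str) -> list[bool]:
    """True where consecutive cysteines are juxtaposed (CC)."""
    import re
    tokens = re.findall(r"(-?)C\d+", notation)
    return [dash == "" for dash in tokens[1:]]


def _sample_signal(rng: np.random.Generator) -> str:
    n_len = int(rng.integers(1, 4))
    h_len = int(rng.integers(10, 13))
    c_len = 3
    return ("M" + _choice(rng, _N_RESIDUES, n_len)
            + _choice(rng, _H_RESIDUES, h_len)
            + _choice(rng, _C_RESIDUES, c_len))


def _sample_propeptide(rng: np.random.Generator) -> str:
    core = _choice(rng, _PRO_RESIDUES, int(rng.integers(5, 16)))
    # quadruplet: at least one acidic residue at P2-P4, arginine at P1
    quad = _choice(rng, "EDAE", 3) + "R"
    if not set(quad[:3]) & set("ED"):
        quad = "E" + quad[1:]
    return core + quad


def _sample_mature(rng: np.random.Generator, scaffold: str) -> str:
    adjacent = _scaffold_gaps(scaffold)
    n_cys = len(adjacent) + 1 if scaffold else 0
    if n_cys == 0:
        return _choice(rng, _LOOP_RESIDUES, int(rng.integers(15, 30)))
    parts = [_choice(rng, _LOOP_RESIDUES, int(rng.integers(3, 9))), "C"]
    for adj in adjacent:
        gap = 0 if adj else int(rng.integers(2, 9))
        parts.append(_choice(rng, _LOOP_RESIDUES_RK, gap))
        parts.append("C")
    parts.append(_choice(rng, _LOOP_RESIDUES_RK, int(rng.integers(2, 7))))
    parts.append(_TERMINAL_RESIDUES[rng.integers(len(_TERMINAL_RESIDUES))])
    return "".join(parts)


@dataclass
class _SeedFamily:
    index: int
    scaffold: str
    signal: str
    propeptide: str        # "" when absent
    mature: str
    amidation: str         # none | G | GK | GR


def sample_seed_families(rng: np.random.Generator,
                         scaffolds: Sequence[str],
                         n_seeds: int,
                         max_cross_identity: float = 20.0) -> list[_SeedFamily]:
    """Draw mutually dissimilar seed precursors, one per family scaffold."""
    from .family import global_identity

    seeds: list[_SeedFamily] = []
    amid_cycle = ("none", "G", "GK", "GR")
    for idx in range(n_seeds):
        scaffold = scaffolds[idx % len(scaffolds)]
        for _attempt in range(50):
            mature = _sample_mature(rng, scaffold)
            if all(global_identity(mature, s.mature) < max_cross_identity
                   for s in seeds):
                break
        with_pro = bool(rng.random() < 0.6)
        seeds.append(_SeedFamily(
            index=idx, scaffold=scaffold,
            signal=_sample_signal(rng),
            propeptide=_sample_propeptide(rng) if with_pro else "",
            mature=mature,
            amidation=amid_cycle[int(rng.integers(len(amid_cycle)))]))
    return seeds


def generate_precursor_cdna(rng: np.random.Generator, scaffold: str,
                            with_propeptide: bool = True,
                            amidation: str = "none") -> tuple[str, ManifestRow]:
    """One toxin precursor cDNA built from scratch (no family context)."""
    seed = _SeedFamily(index=-1, scaffold=scaffold,
                       signal=_sample_signal(rng),
                       propeptide=_sample_propeptide(rng) if with_propeptide else "",
                       mature=_sample_mature(rng, scaffold),
                       amidation=amidation)
    return _emit_toxin_cdna(rng, seed, "toxin")


_AMIDATION_TAILS = {"none": "", "G": "G", "GK": "GK", "GR": "GR"}


def _emit_toxin_cdna(rng: np.random.Generator, fam: _SeedFamily,
                     name: str) -> tuple[str, ManifestRow]:
    tail = _AMIDATION_TAILS[fam.amidation]
    protein = fam.signal + fam.propeptide + fam.mature + tail
    cds = _rt(rng, protein) + _STOPS[rng.integers(3)]
    utr5 = _utr(rng, 20, 60)
    # leading in-frame stop right after the CDS keeps a readthrough
    # extension bounded; the rest emulates realistic 3' UTR lengths
    # (toxin cDNAs run ~0.3-1.0 kb despite short coding regions)
    guard = _choice(rng, "CT", int(rng.integers(6, 16))) + "TAA"
    guard = _choice(rng, "CT", (3 - (len(guard) - 3) % 3) % 3) + guard
    utr3 = guard + _utr(rng, 100, 350)
    polya = "A" * int(rng.integers(12, 25))
    cdna = utr5 + cds + utr3 + polya
    row = ManifestRow(
        id=name, category="toxin_like", family=fam.index,
        protein=protein,
        signal_len=len(fam.signal), pro_len=len(fam.propeptide),
        mature_seq=fam.mature, amidation=fam.amidation,
        framework_notation=extract_framework(fam.mature).notation,
        mature_mass_avg=masscalc.peptide_mass(
            fam.mature, fam.mature.count("C") // 2,
            fam.amidation != "none", scale="average"),
    )
    row._cds_start = len(utr5)  # type: ignore[attr-defined]
    return cdna, row


def _recompute_truth(row: ManifestRow, cdna: str, cds_start: int) -> None:
    """Re-derive protein-level truth from the (possibly mutated) cDNA."""
    protein = _translate(cdna[cds_start:])
    row.protein = protein
    if cdna[cds_start:cds_start + 3] != "ATG":
        row.anomalies.append("lost_start")
    planted_len = row.signal_len + row.pro_len + len(row.mature_seq) \
        + len(_AMIDATION_TAILS[row.amidation])
    mature_start = row.signal_len + row.pro_len
    if len(protein) == planted_len:
        pass  # planted segmentation still valid (substitutions only)
    elif len(protein) < planted_len:
        row.anomalies.append("premature_stop")
        row.completeness = "c_truncated"
        row.amidation = "none"
    else:
        row.anomalies.append("stop_readthrough")
        row.amidation = "none"
    tail_len = len(_AMIDATION_TAILS[row.amidation])
    row.mature_seq = protein[mature_start: len(protein) - tail_len or None]
    fw = extract_framework(row.mature_seq)
    row.framework_notation = fw.notation
    if row.mature_seq:
        n_cys = row.mature_seq.count("C")
        row.mature_mass_avg = masscalc.peptide_mass(
            row.mature_seq, n_cys // 2, row.amidation != "none",
            scale="average") if set(row.mature_seq) <= masscalc.STANDARD_AA else 0.0
    else:
        row.mature_mass_avg = 0.0


def _mutate_point(rng: np.random.Generator, cdna: str, rate: float) -> str:
    if rate <= 0:
        return cdna
    arr = list(cdna)
    n_mut = rng.binomial(len(arr), rate)
    for pos in rng.choice(len(arr), size=min(n_mut, len(arr)), replace=False):
        alt = "ACGT".replace(arr[pos], "")
        arr[pos] = alt[rng.integers(3)]
    return "".join(arr)


def _find_codon(cds: str, cds_start: int, target_aas: str,
                region: tuple[int, int]) -> list[int]:
    """Codon offsets (nt, absolute) within an aa region encoding target residues."""
    out = []
    for aa_idx in range(*region):
        nt = cds_start + 3 * aa_idx
        aa = _CODON_TO_AA.get(cds[nt:nt + 3])
        if aa in target_aas:
            out.append(nt)
    return out


def generate_library(config: GeneratorConfig) -> LibraryBundle:
    """Generate a full library: FASTA records, truth manifest, references, peaks."""
    rng = np.random.default_rng(config.seed)
    seeds = sample_seed_families(rng, config.family_scaffolds, config.n_toxin_seeds)

    # cellular exemplars: synthetic housekeeping-like proteins
    cellular_proteins = [
        "M" + _choice(rng, "ACDEFGHIKLMNPQRSTVWY", int(rng.integers(140, 260)))
        for _ in range(config.n_cellular_exemplars)]
    references = [ReferenceEntry(id=f"TOXREF-{s.index:02d}",
                                 seq=s.signal + s.propeptide + s.mature,
                                 category="toxin", provenance="synthetic-seed")
                  for s in seeds]
    references += [ReferenceEntry(id=f"CELLREF-{i:02d}", seq=p,
                                  category="cellular", provenance="synthetic")
                   for i, p in enumerate(cellular_proteins)]

    n_tox, n_cell, n_none = rng.multinomial(
        config.n_transcripts, config.category_proportions)

    # per-family gene inventory; each gene is one fixed cDNA so that copies
    # of a gene are identical up to per-copy noise and cluster into contigs
    genes: list[_Gene] = []
    for fam in seeds:
        n_genes = 1 + int(rng.poisson(2))
        for _g in range(n_genes):
            variant = _derive_gene_variant(rng, fam)
            cdna, row = _emit_toxin_cdna(rng, variant, "")
            row.gene = f"gene-{len(genes):03d}"
            genes.append(_Gene(index=len(genes), fam=variant, cdna=cdna,
                               cds_start=row._cds_start,  # type: ignore[attr-defined]
                               row=row))
    ranks = np.arange(1, len(genes) + 1, dtype=float)
    weights = ranks ** (-config.copy_zipf_exponent)
    weights /= weights.sum()

    records: list[ESTRecord] = []
    manifest: dict[str, ManifestRow] = {}

    # every planted family is expressed at least once
    fam_first = {g.fam.index: i for i, g in reversed(list(enumerate(genes)))}
    forced = list(fam_first.values())
    picks = list(forced[:n_tox])
    if n_tox > len(picks):
        picks += list(rng.choice(len(genes), size=n_tox - len(picks), p=weights))
    for t_idx, gene_idx in enumerate(picks):
        gene = genes[gene_idx]
        name = f"TOX-{t_idx:04d}"
        row = _copy_row(gene.row, name)
        cdna = _apply_toxin_noise(rng, config, gene.cdna, row, gene.cds_start)
        if rng.random() < config.transcriptome_fraction:
            row.source = "transcriptome"
        cdna, row = _maybe_fragment(rng, config, cdna, row, gene.cds_start)
        records.append(ESTRecord(id=name, seq=cdna, source=row.source))
        manifest[name] = row

    # one fixed cDNA per cellular exemplar as well
    cellular_cdnas = []
    for prot in cellular_proteins:
        cds = _rt(rng, prot) + _STOPS[rng.integers(3)]
        cellular_cdnas.append(_utr(rng, 20, 60) + cds + _utr(rng, 40, 160)
                              + "A" * int(rng.integers(12, 25)))
    for i in range(n_cell):
        name = f"CELL-{i:04d}"
        base = cellular_cdnas[int(rng.integers(len(cellular_cdnas)))]
        cdna = _mutate_point(rng, base, config.point_mutation_rate)
        records.append(ESTRecord(id=name, seq=cdna, source="library"))
        manifest[name] = ManifestRow(id=name, category="cellular")

    for i in range(n_none):
        name = f"NOMATCH-{i:04d}"
        prot = cellular_proteins[int(rng.integers(len(cellular_proteins)))]
        cds = _rt(rng, prot)
        codons = [cds[j:j + 3] for j in range(0, len(cds), 3)]
        rng.shuffle(codons)  # composition-preserving negative control
        cdna = "".join(codons) + "A" * int(rng.integers(12, 25))
        records.append(ESTRecord(id=name, seq=cdna, source="library"))
        manifest[name] = ManifestRow(id=name, category="no_match")

    peaklists = _emit_peaklists(rng, config, manifest)
    return LibraryBundle(records=records, manifest=manifest,
                         references=references, peaklists=peaklists,
                         config=config)


@dataclass
class _Gene:
    index: int
    fam: _SeedFamily
    cdna: str
    cds_start: int
    row: ManifestRow


def _copy_row(template: ManifestRow, name: str) -> ManifestRow:
    row = replace(template, id=name, anomalies=list(template.anomalies))
    row._cds_start = template._cds_start  # type: ignore[attr-defined]
    return row


def _derive_gene_variant(rng: np.random.Generator, fam: _SeedFamily) -> _SeedFamily:
    """A gene of the family: a few loop substitutions in the seed mature."""
    mature = list(fam.mature)
    n_sub = int(rng.poisson(1.5))
    mutable = [i for i, c in enumerate(mature[:-1]) if c != "C"]
    if mutable and n_sub:
        for i in rng.choice(mutable, size=min(n_sub, len(mutable)), replace=False):
            pool = _LOOP_RESIDUES_RK if fam.mature[:i].count("C") else _LOOP_RESIDUES
            mature[i] = pool[rng.integers(len(pool))]
    return replace(fam, mature="".join(mature))


def _apply_toxin_noise(rng: np.random.Generator, config: GeneratorConfig,
                       cdna: str, row: ManifestRow, cds_start: int) -> str:
    mature_aa0 = row.signal_len + row.pro_len
    mature_aa1 = mature_aa0 + len(row.mature_seq)
    mutated = False
    if rng.random() < config.cys_loss_rate:
        targets = _find_codon(cdna, cds_start, "C", (mature_aa0, mature_aa1))
        if targets:
            nt = int(targets[rng.integers(len(targets))])
            cdna = cdna[:nt] + ("AGA" if cdna[nt:nt + 3] == "TGT" else "AGC") \
                + cdna[nt + 3:]
            row.anomalies.append("cys_mutation")
            mutated = True
    if rng.random() < config.stop_gain_rate:
        targets = _find_codon(cdna, cds_start, "Y", (mature_aa0 + 2, mature_aa1))
        if targets:
            nt = int(targets[rng.integers(len(targets))])
            cdna = cdna[:nt] + "TAG" + cdna[nt + 3:]   # UAC -> UAG
            mutated = True
    if rng.random() < config.stop_readthrough_rate:
        stop_nt = cds_start + 3 * (mature_aa1
                                   + len(_AMIDATION_TAILS[row.amidation]))
        if cdna[stop_nt:stop_nt + 3] in _STOPS:
            cdna = cdna[:stop_nt] + "CGA" + cdna[stop_nt + 3:]  # UGA -> CGA
            mutated = True
    before = cdna
    cdna = _mutate_point(rng, cdna, config.point_mutation_rate)
    mutated = mutated or cdna != before
    if mutated:
        _recompute_truth(row, cdna, cds_start)
    return cdna


def _maybe_fragment(rng: np.random.Generator, config: GeneratorConfig,
                    cdna: str, row: ManifestRow, cds_start: int
                    ) -> tuple[str, ManifestRow]:
    if rng.random() >= config.fragmentation_prob:
        return cdna, row
    mature_nt0 = cds_start + 3 * (row.signal_len + row.pro_len)
    if rng.random() < 0.5:
        # 5' loss: cut inside the signal/propeptide region
        hi = max(cds_start + 4, mature_nt0 - 3)
        cut = int(rng.integers(cds_start + 3, hi)) if hi > cds_start + 3 else cds_start + 3
        cdna = cdna[cut:]
        row.fragmented = "5p"
        row.completeness = "n_truncated"
    else:
        # 3' loss: drop the poly-A, UTR and stop codon
        stop_nt = cds_start + 3 * len(row.protein)
        lo = max(mature_nt0 + 6, stop_nt - 15)
        if lo > stop_nt:   # protein already too short to trim further
            return cdna, row
        cut = int(rng.integers(lo, stop_nt + 1))
        cdna = cdna[:cut]
        row.fragmented = "3p"
        row.completeness = "c_truncated"
        keep_aa = (cut - cds_start) // 3
        row.mature_seq = row.protein[row.signal_len + row.pro_len: keep_aa]
        row.protein = row.protein[:keep_aa]
        row.amidation = "none"
        row.framework_notation = extract_framework(row.mature_seq).notation
        row.mature_mass_avg = masscalc.peptide_mass(
            row.mature_seq, row.mature_seq.count("C") // 2, False,
            scale="average") if row.mature_seq and not (
                set(row.mature_seq) - masscalc.STANDARD_AA) else 0.0
    return cdna, row


def _emit_peaklists(rng: np.random.Generator, config: GeneratorConfig,
                    manifest: dict[str, ManifestRow]) -> list[PeakList]:
    masses = sorted({round(r.mature_mass_avg, 4) for r in manifest.values()
                     if r.category == "toxin_like" and r.completeness == "full_length"
                     and not r.anomalies and 1000 < r.mature_mass_avg < 10000})
    if not masses:
        return []
    chunks = np.array_split(np.asarray(masses), config.n_fractions)
    peaklists = []
    for f_idx, chunk in enumerate(chunks):
        peaks: list[tuple[float, float]] = []
        for m in chunk:
            peaks.append((m + masscalc.PROTON_MASS, float(rng.uniform(50, 100))))
            if rng.random() < 0.3:
                peaks.append(((m + 2 * masscalc.PROTON_MASS) / 2.0,
                              float(rng.uniform(10, 40))))
        for _ in range(config.noise_peaks_per_fraction):
            peaks.append((float(rng.uniform(1000, 10000)),
                          float(rng.uniform(1, 10))))
        peaklists.append(PeakList(fraction=f"F{f_idx + 1:02d}", peaks=peaks))
    return peaklists


def manifest_to_dict(bundle: LibraryBundle) -> dict:
    """JSON-serializable ground-truth manifest."""
    return {
        rid: {
            "category": row.category, "source": row.source,
            "family": row.family, "gene": row.gene,
            "signal_len": row.signal_len, "pro_len": row.pro_len,
            "mature_seq": row.mature_seq, "amidation": row.amidation,
            "framework": row.framework_notation,
            "mature_mass_avg": round(row.mature_mass_avg, 4),
            "completeness": row.completeness,
            "anomalies": row.anomalies, "fragmented": row.fragmented,
        }
        for rid, row in bundle.manifest.items()
    }
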