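"""Reading, writing and quality control of EST and reference sequence sets.

A venom-gland cDNA library yields single-pass clone reads (ESTs); a
transcriptome assembly contributes additional toxin-like transcripts.  Both
arrive as nucleotide FASTA.  Quality control keeps inserts strictly longer
than a length floor (default 300 nt), mirroring the common definition of a
high-quality EST for Sanger-sequenced library clones.

Peak lists from MALDI-TOF analysis of HPLC fractions are consumed as
two-column tab- or whitespace-separated text (m/z, intensity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# IUPAC nucleotide codes (no gaps).
DNA_LETTERS = frozenset("ACGTNRYSWKMBDHV")
PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZJUO" + "*")

DEFAULT_QC_MIN_LEN = 300


@dataclass
class ESTRecord:
    """One nucleotide sequence tagged with its sequencing source."""

    id: str
    seq: str
    source: str = "library"  # "library" | "transcriptome"
    is_high_quality: bool = False
    category: str | None = None  # filled in by annotation

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if self.source not in ("library", "transcriptome"):
            raise ValueError(f"unknown source {self.source!r} for {self.id}")
        bad = set(self.seq) - DNA_LETTERS
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-IUPAC DNA characters: {sorted(bad)}"
            )

    @property
    def length_nt(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceEntry:
    """A protein exemplar used for annotation (toxin or cellular)."""

    id: str
    seq: str
    category: str  # "toxin" | "cellular"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"reference {self.id!r} has an empty sequence")
        if self.category not in ("toxin", "cellular"):
            raise ValueError(f"reference {self.id!r}: bad category {self.category!r}")


@dataclass
class PeakList:
    """MALDI-TOF peaks of one HPLC fraction, sorted ascending by m/z."""

    fraction: str
    peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for mz, inten in self.peaks:
            if mz < 0:
                raise ValueError(f"negative m/z {mz} in fraction {self.fraction}")
            if inten < 0:
                raise ValueError(f"negative intensity {inten} in fraction {self.fraction}")
        self.peaks = sorted(self.peaks)

    @property
    def mz_values(self) -> list[float]:
        return [mz for mz, _ in self.peaks]

    def __len__(self) -> int:
        return len(self.peaks)


def _check_alphabet(name: str, seq: str, alphabet: str) -> None:
    letters = DNA_LETTERS if alphabet == "dna" else PROTEIN_LETTERS
    if "-" in seq or "." in seq:
        raise ValueError(f"record {name!r} contains gap characters")
    bad = set(seq) - letters
    if bad:
        raise ValueError(
            f"record {name!r} contains characters outside the {alphabet} "
            f"alphabet: {sorted(bad)}"
        )


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[tuple[str, str, str]]:
    """Read a FASTA file into ``(id, sequence, description)`` tuples.

    Sequences are upper-cased; duplicate ids, gap characters and letters
    outside the chosen alphabet are hard errors.
    """
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"alphabet must be 'dna' or 'protein', got {alphabet!r}")
    out: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        _check_alphabet(rec.id, seq, alphabet)
        out.append((rec.id, seq, rec.description))
    return out


def write_fasta(records: Iterable[tuple[str, str] | tuple[str, str, str]],
                path: str | Path, width: int = 60) -> None:
    """Write ``(id, seq[, description])`` tuples as wrapped FASTA."""
    seqrecs = []
    for tup in records:
        rid, seq = tup[0], tup[1]
        desc = tup[2] if len(tup) > 2 else ""
        # SeqIO prepends the id to the description unless they coincide
        if desc.startswith(rid):
            desc = desc[len(rid):].strip()
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def load_ests(path: str | Path, source: str = "library") -> list[ESTRecord]:
    """Load a nucleotide FASTA as ESTRecords with a common source tag."""
    return [ESTRecord(id=rid, seq=seq, source=source)
            for rid, seq, _ in read_fasta(path, "dna")]


def load_references(path: str | Path) -> list[ReferenceEntry]:
    """Load a protein FASTA whose descriptions carry ``category=...`` tags.

    Records without a tag default to category ``toxin``.
    """
    refs = []
    for rid, seq, desc in read_fasta(path, "protein"):
        category = "toxin"
        provenance = ""
        for tok in desc.split():
            if tok.startswith("category="):
                category = tok.split("=", 1)[1]
            elif tok.startswith("provenance="):
                provenance = tok.split("=", 1)[1]
        refs.append(ReferenceEntry(id=rid, seq=seq.rstrip("*"),
                                   category=category, provenance=provenance))
    return refs


def trim_flanks(seq: str, five_prime: str | None = None,
                three_prime: str | None = None) -> str:
    """Strip one 5' and/or 3' flanking motif (vector/adapter remnant) if present.

    Input is otherwise assumed to be insert-only; trimming is opt-in.
    """
    s = seq.upper()
    if five_prime:
        idx = s.find(five_prime.upper())
        if idx != -1:
            s = s[idx + len(five_prime):]
    if three_prime:
        idx = s.rfind(three_prime.upper())
        if idx != -1:
            s = s[:idx]
    return s


def qc_filter(records: Sequence[ESTRecord],
              qc_min_len: int = DEFAULT_QC_MIN_LEN) -> tuple[list[ESTRecord], list[ESTRecord]]:
    """Split records into (passing, failing) by the strict length filter.

    A record passes iff its length is strictly greater than ``qc_min_len``.
    Input order is preserved in both outputs and the two lists partition the
    input.
    """
    if qc_min_len < 0:
        raise ValueError("qc_min_len must be >= 0")
    passing: list[ESTRecord] = []
    failing: list[ESTRecord] = []
    for rec in records:
        if rec.length_nt > qc_min_len:
            rec.is_high_quality = True
            passing.append(rec)
        else:
            rec.is_high_quality = False
            failing.append(rec)
    return passing, failing


def read_peaklist(path: str | Path, fraction: str | None = None) -> PeakList:
    """Read a two-column (m/z, intensity) text file; one header line allowed."""
    path = Path(path)
    peaks: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            try:
                mz = float(parts[0])
                inten = float(parts[1]) if len(parts) > 1 else 0.0
            except ValueError:
                if lineno == 0:  # tolerated header
                    continue
                raise ValueError(f"{path}:{lineno + 1}: cannot parse peak line {line!r}")
            peaks.append((mz, inten))
    return PeakList(fraction=fraction or path.stem, peaks=peaks)


def write_peaklist(peaklist: PeakList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mz\tintensity\n")
        for mz, inten in peaklist.peaks:
            fh.write(f"{mz:.4f}\t{inten:.2f}\n")


def write_manifest(manifest: dict, path: str | Path) -> None:
    """Serialize a run/ground-truth manifest as sorted-key JSON."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
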