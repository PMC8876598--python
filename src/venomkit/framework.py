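"""Cysteine frameworks and disulfide-connectivity templates.

A mature toxin's cysteine framework is written in adjacency notation:
cysteines are numbered C1..Cn in sequence order, separated by a dash
unless they are immediately adjacent in the sequence, in which case they
are juxtaposed (e.g. ``C1-C2-C3C4-C5-C6`` — the classic six-cysteine
inhibitor cystine knot arrangement, where C3 and C4 are neighbours).

Frameworks are matched exactly against a registry of connectivity
templates (ICK, MIT1-like ten-cysteine, etc.); a framework whose notation
matches no template — or more than one, as with the plain six-cysteine
pattern shared by Kunitz and DDH scaffolds — is left unassigned rather
than guessed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib


@dataclass
class CysteineFramework:
    positions: list[int]  # 1-based cysteine indices in the mature peptide
    notation: str = ""
    template_id: str | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def n_cys(self) -> int:
        return len(self.positions)

    @property
    def adjacency_signature(self) -> str:
        """'1' where consecutive cysteines are sequence-adjacent, else '0'."""
        return "".join(
            "1" if b - a == 1 else "0"
            for a, b in zip(self.positions, self.positions[1:]))


@dataclass(frozen=True)
class DisulfideTemplate:
    id: str
    n_cys: int
    pairs: tuple[tuple[int, int], ...]
    notation: str
    description: str = ""

    def __post_init__(self) -> None:
        paired = [c for p in self.pairs for c in p]
        if len(set(paired)) != len(paired):
            raise ValueError(f"template {self.id}: repeated cysteine in pairing")
        if any(c < 1 or c > self.n_cys for c in paired):
            raise ValueError(f"template {self.id}: pair index out of range")


#: Bundled connectivity templates.  Kunitz and DDH share the plain
#: six-cysteine notation and are therefore never assigned by notation alone.
TEMPLATE_REGISTRY: tuple[DisulfideTemplate, ...] = (
    DisulfideTemplate("ICK-6", 6, ((1, 4), (2, 5), (3, 6)),
                      "C1-C2-C3C4-C5-C6", "inhibitor cystine knot"),
    DisulfideTemplate("Kunitz-6", 6, ((1, 6), (2, 4), (3, 5)),
                      "C1-C2-C3-C4-C5-C6", "Kunitz protease-inhibitor fold"),
    DisulfideTemplate("DDH-6", 6, ((1, 3), (2, 5), (4, 6)),
                      "C1-C2-C3-C4-C5-C6", "disulfide-directed beta-hairpin"),
    DisulfideTemplate("MIT1-10", 10, ((1, 4), (2, 5), (3, 7), (6, 9), (8, 10)),
                      "C1-C2-C3C4-C5-C6-C7-C8-C9-C10",
                      "MIT1-like ten-cysteine mode"),
    DisulfideTemplate("familyB-10", 10, ((1, 7), (2, 8), (3, 6), (4, 10), (5, 9)),
                      "C1-C2-C3C4-C5-C6C7-C8-C9-C10",
                      "ten-cysteine mode with two adjacent pairs"),
    DisulfideTemplate("ICK-like-8", 8, ((1, 4), (2, 5), (3, 8), (6, 7)),
                      "C1-C2-C3C4-C5-C6-C7-C8", "eight-cysteine ICK extension"),
)


def extract_framework(mature: str) -> CysteineFramework:
    """Cysteine positions and adjacency notation of a mature peptide."""
    seq = mature.upper()
    positions = [i + 1 for i, c in enumerate(seq) if c == "C"]
    fw = CysteineFramework(positions=positions)
    fw.notation = notation_from_positions(positions)
    return fw


def notation_from_positions(positions: list[int]) -> str:
    parts: list[str] = []
    for k, pos in enumerate(positions, start=1):
        label = f"C{k}"
        if k == 1:
            parts.append(label)
        elif pos - positions[k - 2] == 1:
            parts.append(label)          # juxtapose: adjacent in sequence
        else:
            parts.append("-" + label)
    return "".join(parts)


def parse_notation(notation: str) -> tuple[int, str]:
    """Return (n_cys, adjacency signature) from a notation string."""
    if not notation:
        return 0, ""
    tokens = re.findall(r"(-?)C\d+", notation)
    n = len(tokens)
    signature = "".join("0" if dash else "1" for dash in tokens[1:])
    return n, signature


def assign_template(framework: CysteineFramework,
                    registry: tuple[DisulfideTemplate, ...] = TEMPLATE_REGISTRY
                    ) -> str | None:
    """Assign a disulfide template by exact notation match, or None.

    A notation matching several registered templates (indistinguishable by
    spacing alone) is reported as unassigned with an ``ambiguous_template``
    note; odd cysteine counts get an ``unpaired_cys`` note.
    """
    if framework.n_cys % 2 == 1 and framework.n_cys > 0:
        if "unpaired_cys" not in framework.notes:
            framework.notes.append("unpaired_cys")
    matches = [t for t in registry
               if t.n_cys == framework.n_cys and t.notation == framework.notation]
    if len(matches) == 1:
        framework.template_id = matches[0].id
        return matches[0].id
    if len(matches) > 1 and "ambiguous_template" not in framework.notes:
        framework.notes.append("ambiguous_template")
    framework.template_id = None
    return None


def template_by_id(template_id: str,
                   registry: tuple[DisulfideTemplate, ...] = TEMPLATE_REGISTRY
                   ) -> DisulfideTemplate:
    for t in registry:
        if t.id == template_id:
            return t
    raise KeyError(template_id)


def framework_distance(a: CysteineFramework, b: CysteineFramework) -> int:
    """Dissimilarity of two frameworks.

    Levenshtein distance between the adjacency signatures plus the
    absolute cysteine-count difference; zero iff the notations coincide.
    """
    sig_a, sig_b = a.adjacency_signature, b.adjacency_signature
    if sig_a == sig_b:
        edit = 0
    elif not sig_a or not sig_b:
        edit = max(len(sig_a), len(sig_b))
    else:
        edit = edlib.align(sig_a, sig_b)["editDistance"]
    return edit + abs(a.n_cys - b.n_cys)
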