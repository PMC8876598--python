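"""venomkit: venom-gland EST/transcriptome toxin discovery.

Quality control and annotation of venom-gland cDNA-library and
transcriptome sequences, contig clustering, toxin precursor segmentation
(signal peptide / PQM propeptide / mature peptide), cysteine-framework
and disulfide-template assignment, family grouping, and theoretical-mass
cross-validation against MALDI-TOF peak lists — plus a synthetic library
generator with exact ground truth for end-to-end validation.
"""

from importlib.resources import files as _files

__version__ = "0.1.0"

from . import (annotate, cluster, family, framework, masscalc, pipeline,
               precursor, seqio, synthetic)  # noqa: F401


def default_reference_path() -> str:
    """Path of the bundled reference exemplar FASTA."""
    return str(_files("venomkit") / "data" / "reference_exemplars.synthetic.fasta")
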