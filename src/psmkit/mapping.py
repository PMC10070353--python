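"""Peptide-to-protein coordinate mapping for PTM sites.

Positions are 1-based inclusive on both the peptide and the protein.  A
modified lysine rendered as lowercase ``"k"`` in the peptide matches the
upper-case ``K`` of the protein sequence.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ProteinSite:
    """One mapped modification site on a protein."""

    accession: str
    position: int  # 1-based protein coordinate
    residue: str
    mod_type: str
    multimapped: bool = False  # peptide occurs more than once in the protein


def map_peptide_to_sites(sequence, modifications, accession, protein_seq):
    """Map peptide modification positions onto protein coordinates.

    The leftmost occurrence of the peptide in the protein is used; if the
    peptide occurs more than once, emitted sites carry ``multimapped=True``.
    Raises ``ValueError`` when the peptide is absent from the protein.
    """
    pep = sequence.upper()
    prot = protein_seq.upper()
    offset = prot.find(pep)
    if offset < 0:
        raise ValueError(
            f"peptide {sequence!r} not found in protein {accession!r}"
        )
    multimapped = prot.find(pep, offset + 1) >= 0
    sites = []
    for pep_pos, mod_type in modifications:
        prot_pos = offset + pep_pos  # offset is 0-based, pep_pos 1-based
        residue = prot[prot_pos - 1]
        assert residue == pep[pep_pos - 1], "residue mismatch after mapping"
        sites.append(
            ProteinSite(accession, prot_pos, residue, mod_type, multimapped)
        )
    return sites
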