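"""HLA-I / HLA-II immunopeptidome filtering and summary statistics.

The filter chain mirrors the order in which an immunopeptidome dataset
is cleaned: spectral quality (sequence tag length, precursor MH+ range),
per-class PSM thresholds (length, backbone cleavage score, precursor
charge), pooled 1% target-decoy FDR across fractions, contaminant
removal (blank-bead IP list, tryptic list, non-human annotations),
modified-peptide quality (score > 6, SPI > 60%), and for HLA-I a final
8-11mer length restriction.  Every removal is attributed to exactly one
named stage in the audit log.

Summaries: peptide length histograms, column-normalized position
frequency (motif) matrices, HLA-II nested-set grouping via shared
binding cores, and PTM position distributions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import fdr
from .profiles import HLA_I, HLA_II
from .types import FilterProfile

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

MIN_HLA_PEPTIDE_LENGTH = 7
MIN_HLA_BCS = 5.0
HLA1_REPORT_LENGTHS = (8, 11)  # final HLA-I report: 8-11mers only
MODIFIED_MIN_SCORE = 6.0  # strict >
MODIFIED_MIN_SPI = 60.0  # strict >
DEFAULT_CORE_LENGTH = 9  # typical HLA class II binding core


@dataclass
class FilterAudit:
    """Stage-attributed removal log for one filter-chain invocation."""

    n_input: int = 0
    stages: list = field(default_factory=list)  # (stage name, n removed)

    def record(self, stage: str, before: int, after: int):
        self.stages.append((stage, before - after))

    @property
    def n_removed(self) -> int:
        return sum(n for _, n in self.stages)


def spectral_quality_filter(psms, mode: str = "hla"):
    """Sequence-tag-length and precursor MH+ range filter.

    ``hla`` mode: tag length > 1, MH+ within 600-4000 (inclusive);
    ``global`` mode: tag length > 0, MH+ within 800-6000.  Records with
    unknown tag length pass the tag criterion.
    """
    if mode == "hla":
        min_tag, mh_range = 2, (600.0, 4000.0)
    elif mode == "global":
        min_tag, mh_range = 1, (800.0, 6000.0)
    else:
        raise ValueError(f"unknown spectral quality mode {mode!r}")
    lo, hi = mh_range
    return [
        p
        for p in psms
        if (p.tag_length is None or p.tag_length >= min_tag)
        and lo <= p.precursor_mh <= hi
    ]


def hla_psm_filter(psms, hla_class: str, fdr_target: float = 0.01):
    """Class-specific PSM thresholds followed by pooled FDR control.

    Length >= 7, BCS >= 5, charge within the class range (HLA-I: 1-4,
    HLA-II: 2-6), then autovalidation pooled across all fractions at the
    1% FDR budget.  Returns ``(accepted, threshold_sets)``.
    """
    profile = _class_profile(hla_class)
    lo_z, hi_z = profile.charge_range
    prefiltered = [
        p
        for p in psms
        if len(p.sequence) >= MIN_HLA_PEPTIDE_LENGTH
        and p.bcs >= MIN_HLA_BCS
        and lo_z <= p.charge <= hi_z
    ]
    threshold_sets, accepted = fdr.autovalidate(
        prefiltered, fdr.hla_buckets(profile.charge_range, fdr_target)
    )
    return accepted, threshold_sets


def _class_profile(hla_class: str) -> FilterProfile:
    if hla_class in ("I", "HLA-I"):
        return HLA_I
    if hla_class in ("II", "HLA-II"):
        return HLA_II
    raise ValueError(f"unknown HLA class {hla_class!r}")


def contaminant_filter(psms, blank_bead_list, tryptic_list,
                       species_annotation=None):
    """Remove contaminant and non-human peptides.

    Exact-sequence removal against the blank-bead and tryptic contaminant
    lists; ``species_annotation`` maps protein accession -> species token,
    and a PSM whose candidate proteins are all annotated non-human is
    removed.  Returns ``(retained, removal_audit)`` where the audit maps
    reason -> removed count.
    """
    if blank_bead_list is None or tryptic_list is None:
        raise ValueError("contaminant lists are required (may be empty sets)")
    species_annotation = species_annotation or {}
    retained = []
    audit = Counter()
    for p in psms:
        seq = p.sequence.upper()
        if seq in blank_bead_list:
            audit["blank_bead"] += 1
        elif seq in tryptic_list:
            audit["tryptic"] += 1
        elif p.candidate_proteins and all(
            species_annotation.get(acc, "human") != "human"
            for acc in p.candidate_proteins
        ):
            audit["non_human"] += 1
        else:
            retained.append(p)
    return retained, dict(audit)


def modified_hla_filter(psms):
    """Quality filter for phospho/acetyl HLA peptides.

    Modified peptides must have score > 6 and SPI > 60% (both strict);
    unmodified peptides pass unchanged.
    """
    return [
        p
        for p in psms
        if not p.modifications
        or (p.score > MODIFIED_MIN_SCORE and p.spi_pct > MODIFIED_MIN_SPI)
    ]


def hla_class1_final_filter(psms):
    """Restrict the final HLA-I report to 8-11mers."""
    lo, hi = HLA1_REPORT_LENGTHS
    return [p for p in psms if lo <= len(p.sequence) <= hi]


def run_hla_pipeline(psms, hla_class: str, blank_bead_list=frozenset(),
                     tryptic_list=frozenset(), species_annotation=None,
                     fdr_target: float = 0.01, apply_fdr: bool = True):
    """Full immunopeptidome filter chain with a stage-attributed audit.

    Stage order: spectral quality -> class PSM filters -> FDR ->
    contaminants -> modified-peptide quality -> (HLA-I only) 8-11mer
    restriction.  ``apply_fdr=False`` skips the pooled FDR stage (useful
    for decoy-free inputs).  Returns ``(accepted_psms, audit,
    threshold_sets)``.
    """
    audit = FilterAudit(n_input=len(psms))
    current = spectral_quality_filter(psms, "hla")
    audit.record("spectral_quality", len(psms), len(current))

    n = len(current)
    profile = _class_profile(hla_class)
    lo_z, hi_z = profile.charge_range
    prefiltered = [
        p
        for p in current
        if len(p.sequence) >= MIN_HLA_PEPTIDE_LENGTH
        and p.bcs >= MIN_HLA_BCS
        and lo_z <= p.charge <= hi_z
    ]
    audit.record("length_bcs_charge", n, len(prefiltered))
    threshold_sets = []
    if apply_fdr:
        threshold_sets, accepted = fdr.autovalidate(
            prefiltered, fdr.hla_buckets(profile.charge_range, fdr_target)
        )
        audit.record("fdr", len(prefiltered), len(accepted))
        current = accepted
    else:
        current = prefiltered

    n = len(current)
    current, _ = contaminant_filter(
        current, blank_bead_list, tryptic_list, species_annotation
    )
    audit.record("contaminants", n, len(current))

    n = len(current)
    current = modified_hla_filter(current)
    audit.record("modified_quality", n, len(current))

    if hla_class in ("I", "HLA-I"):
        n = len(current)
        current = hla_class1_final_filter(current)
        audit.record("hla1_length_8_11", n, len(current))

    return current, audit, threshold_sets


# ---------------------------------------------------------------------------
# summaries


def length_distribution(peptides) -> dict:
    """Peptide length histogram {length: count}."""
    return dict(Counter(len(p) for p in peptides))


def position_frequency_matrix(peptides) -> np.ndarray:
    """Column-normalized 20 x L residue frequency matrix.

    Rows follow :data:`AMINO_ACIDS`; entry (aa, pos) is the fraction of
    peptides carrying ``aa`` at ``pos``.  All peptides must share one
    length.
    """
    peptides = [p.upper() for p in peptides]
    if not peptides:
        raise ValueError("no peptides")
    lengths = {len(p) for p in peptides}
    if len(lengths) != 1:
        raise ValueError(f"mixed peptide lengths: {sorted(lengths)}")
    length = lengths.pop()
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    pfm = np.zeros((len(AMINO_ACIDS), length))
    for pep in peptides:
        for pos, aa in enumerate(pep):
            pfm[index[aa], pos] += 1
    return pfm / len(peptides)


def nested_set_grouping(peptides, core_length: int = DEFAULT_CORE_LENGTH):
    """Group HLA-II peptides into nested sets.

    Two peptides connect when one contains the other as a substring or
    they share a common substring of at least ``core_length`` residues
    (the binding core); groups are the transitive closure.  Returns a
    partition of the input as a list of sorted peptide lists.
    """
    peptides = list(dict.fromkeys(peptides))  # dedupe, keep order
    graph = nx.Graph()
    graph.add_nodes_from(peptides)
    kmer_index = {}
    for pep in peptides:
        for i in range(len(pep) - core_length + 1):
            kmer_index.setdefault(pep[i : i + core_length], []).append(pep)
    for members in kmer_index.values():
        graph.add_edges_from((members[0], m) for m in members[1:])
    # containment can connect peptides shorter than the core length
    short = [p for p in peptides if len(p) < core_length]
    for p in short:
        for q in peptides:
            if p is not q and p in q:
                graph.add_edge(p, q)
    return sorted(
        sorted(component) for component in nx.connected_components(graph)
    )


def ptm_position_summary(psms) -> dict:
    """Distribution of modification positions: {position: fraction}.

    Counts every modification on every modified peptide; fractions sum
    to 1.  Empty input yields an empty dict.
    """
    counts = Counter(
        pos for p in psms for pos, _ in p.modifications
    )
    total = sum(counts.values())
    return {pos: n / total for pos, n in sorted(counts.items())}
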