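"""Protein group closure, subgroup expansion and protein polishing.

Proteins fall in the same group when they share a peptide longer than 8
residues (shorter peptides never create edges but still count as
evidence).  Within a group, subgroups are seeded by unique-peptide
support; under "expand subgroups, top uses shared" each shared peptide is
allocated to the highest-scoring subgroup containing it, in a single
pass using the unique-peptide score ranking computed once.  The protein
score is the sum of the scores of allocated distinct peptides, a distinct
peptide being the single highest-scoring instance of a peptide sequence.

Two polishing passes control protein-level FDR:

* within each plex, every PSM contributing to a protein group scoring
  below the best group made up entirely of presumed-false peptides
  (negative delta forward-reverse score) is removed;
* across plexes, subgroups survive only with a protein score >= 25 or
  observation in at least two plexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .types import ProteinSubgroup, PSMRecord

MIN_SHARED_PEPTIDE_LENGTH = 9  # strictly > 8 residues


@dataclass
class PeptideEvidence:
    """All evidence for one distinct peptide sequence."""

    sequence: str
    best_psm: PSMRecord
    proteins: set = field(default_factory=set)
    plexes: set = field(default_factory=set)
    psms: list = field(default_factory=list)

    @property
    def score(self) -> float:
        return self.best_psm.score


def build_peptide_evidence(psms) -> dict:
    """Collapse PSMs into distinct peptides (best PSM per sequence).

    The best PSM is the highest-scoring one, ties broken by smallest
    spectrum_id; protein and plex evidence is the union over all PSMs of
    the sequence.
    """
    evidence = {}
    for psm in psms:
        ev = evidence.get(psm.sequence)
        if ev is None:
            ev = PeptideEvidence(psm.sequence, psm)
            evidence[psm.sequence] = ev
        elif psm.score > ev.best_psm.score or (
            psm.score == ev.best_psm.score
            and psm.spectrum_id < ev.best_psm.spectrum_id
        ):
            ev.best_psm = psm
        ev.proteins.update(psm.candidate_proteins)
        ev.plexes.add(psm.plex_id)
        ev.psms.append(psm)
    return evidence


def build_groups(evidence: dict):
    """Protein groups: connected components over shared long peptides.

    Returns a sorted list of sorted accession tuples.  Every protein with
    any peptide evidence appears in exactly one group.
    """
    graph = nx.Graph()
    for ev in evidence.values():
        graph.add_nodes_from(ev.proteins)
        if len(ev.sequence) >= MIN_SHARED_PEPTIDE_LENGTH:
            proteins = sorted(ev.proteins)
            graph.add_edges_from(
                (proteins[0], other) for other in proteins[1:]
            )
    return sorted(
        tuple(sorted(component))
        for component in nx.connected_components(graph)
    )


def _subgroup_members(group, pepsets):
    """Partition a group's proteins into subgroups.

    Proteins with identical peptide-evidence sets coalesce; a protein
    whose evidence is a strict subset of another's folds into the largest
    such superset protein (accession order breaking ties), so only
    proteins with uniquely representing peptides seed subgroups.
    """
    clusters = {}
    for accession in group:
        clusters.setdefault(frozenset(pepsets[accession]), []).append(accession)
    keys = sorted(clusters, key=lambda k: (-len(k), clusters[k][0]))
    maximal = [
        k for k in keys
        if not any(k < other for other in clusters if len(other) > len(k))
    ]
    assignment = {k: k for k in maximal}
    for k in keys:
        if k in assignment:
            continue
        supersets = [m for m in maximal if k < m]
        # a non-maximal cluster always has a maximal superset
        target = min(supersets, key=lambda m: (-len(m), clusters[m][0]))
        assignment[k] = target
    subgroups = {}
    for k, target in assignment.items():
        subgroups.setdefault(target, []).extend(clusters[k])
    return [tuple(sorted(members)) for members in subgroups.values()]


def expand_subgroups(group, evidence: dict, mode: str = "top_uses_shared",
                     group_id: int = -1):
    """Expand one protein group into scored subgroups.

    ``top_uses_shared`` allocates each shared peptide to the
    highest-scoring subgroup containing it (unique-peptide scores ranked
    once; accession-lexicographic tie-break).  ``unexpand`` collapses the
    group to a single reporting unit labeled by its top subgroup, with
    every distinct peptide counted once.
    """
    if mode not in ("top_uses_shared", "unexpand"):
        raise ValueError(f"unknown grouping mode {mode!r}")
    group = tuple(sorted(group))
    group_set = set(group)
    peptides = [
        ev for ev in evidence.values() if ev.proteins & group_set
    ]
    pepsets = {acc: set() for acc in group}
    for ev in peptides:
        for acc in ev.proteins & group_set:
            pepsets[acc].add(ev.sequence)

    members_list = _subgroup_members(group, pepsets)
    member_index = {
        acc: i for i, members in enumerate(members_list) for acc in members
    }

    unique_peps = [[] for _ in members_list]
    shared_peps = []
    for ev in sorted(peptides, key=lambda e: e.sequence):
        owners = {member_index[acc] for acc in ev.proteins & group_set}
        if len(owners) == 1:
            unique_peps[owners.pop()].append(ev)
        else:
            shared_peps.append((ev, owners))

    base_scores = [sum(ev.score for ev in peps) for peps in unique_peps]
    allocations = [list(peps) for peps in unique_peps]
    for ev, owners in shared_peps:
        # rank by unique-peptide score computed once; ties by accession
        best = min(owners, key=lambda i: (-base_scores[i], members_list[i][0]))
        allocations[best].append(ev)

    subgroups = []
    for members, peps in zip(members_list, allocations):
        best_psms = {ev.sequence: ev.best_psm for ev in peps}
        subgroups.append(
            ProteinSubgroup(
                members=members,
                peptides=best_psms,
                score=sum(p.score for p in best_psms.values()),
                plexes=frozenset().union(*(ev.plexes for ev in peps))
                if peps else frozenset(),
                all_false=bool(peps)
                and all(p.delta_fr_score < 0 for p in best_psms.values()),
                group_id=group_id,
            )
        )
    subgroups.sort(key=lambda sg: (-sg.score, sg.members))

    if mode == "unexpand":
        all_peps = {ev.sequence: ev for ev in peptides}
        best_psms = {seq: ev.best_psm for seq, ev in sorted(all_peps.items())}
        return [
            ProteinSubgroup(
                members=subgroups[0].members,
                peptides=best_psms,
                score=sum(p.score for p in best_psms.values()),
                plexes=frozenset().union(
                    *(ev.plexes for ev in all_peps.values())
                ) if all_peps else frozenset(),
                all_false=bool(best_psms)
                and all(p.delta_fr_score < 0 for p in best_psms.values()),
                group_id=group_id,
            )
        ]
    return subgroups


def group_and_expand(psms, mode: str = "top_uses_shared"):
    """Full grouping pass: evidence -> groups -> scored subgroups."""
    evidence = build_peptide_evidence(psms)
    groups = build_groups(evidence)
    subgroups = []
    for gid, group in enumerate(groups):
        subgroups.extend(expand_subgroups(group, evidence, mode, group_id=gid))
    return subgroups


def false_positive_score_threshold(subgroups) -> float:
    """Best protein score among subgroups made entirely of presumed-false
    peptides (negative delta forward-reverse score); 0 when none exist."""
    scores = [sg.score for sg in subgroups if sg.all_false]
    return max(scores) if scores else 0.0


def polish_within_plex(psms):
    """Within-plex protein polishing at a protein-level FDR target of zero.

    Groups are assembled per plex; every PSM whose peptide was allocated
    to a subgroup scoring strictly below the maximum all-false subgroup
    score is removed (subgroups scoring exactly at the threshold are
    kept).  PSMs without protein evidence are retained untouched.
    Returns the surviving PSMs in input order.
    """
    by_plex = {}
    for psm in psms:
        by_plex.setdefault(psm.plex_id, []).append(psm)
    removed = set()
    for plex_psms in by_plex.values():
        groupable = [p for p in plex_psms if p.candidate_proteins]
        evidence = build_peptide_evidence(groupable)
        groups = build_groups(evidence)
        subgroups = []
        for gid, group in enumerate(groups):
            subgroups.extend(
                expand_subgroups(group, evidence, "top_uses_shared", gid)
            )
        threshold = false_positive_score_threshold(subgroups)
        if threshold <= 0:
            continue
        for sg in subgroups:
            if sg.score < threshold:
                for seq in sg.peptides:
                    removed.update(id(p) for p in evidence[seq].psms)
    return [p for p in psms if id(p) not in removed]


def polish_cross_plex(subgroups, min_score: float = 25.0, min_plexes: int = 2):
    """Cross-plex protein polishing.

    Retain subgroups with a protein score >= ``min_score`` (inclusive) or
    observation in at least ``min_plexes`` plexes — removing low-scoring
    proteins detected in only one plex.
    """
    return [
        sg
        for sg in subgroups
        if sg.score >= min_score or len(sg.plexes) >= min_plexes
    ]
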