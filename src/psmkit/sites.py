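"""Variable-modification (VM) site confidence, aggregation and polishing.

A localization score is the identification-score gap between the two best
site placements for a modified peptide; a gap > 1.1 marks the site as
confidently localized.  Observations of the same site across charge
states, missed-cleavage forms and plexes are merged into single VM-site
rows, never combining observations that disagree on the modification
count or on confidently localized positions.  An ambiguous observation's
candidate position set is the set of acceptor residues (STY for phospho,
K for acetyl/diGly) covered by its peptide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .mapping import map_peptide_to_sites
from .types import MOD_ACCEPTOR_RESIDUES, VMSiteRecord

LOCALIZATION_GAP = 1.1  # strict: confident iff top - second > 1.1

#: ion-type scores applied upstream by the search engine to neutral-loss
#: ion types (b/y - H3PO4 and b/y - H2O); recorded as provenance metadata,
#: never recomputed here
NEUTRAL_LOSS_ION_TYPE_SCORE = 0.5

CTERM_MOD_LYSINE_RE = re.compile(r"[^K][^K]k$")


def classify_localization(top_score, second_score=None) -> bool:
    """Confident iff the top-two localization score gap exceeds 1.1.

    A single-candidate localization (``second_score`` absent) is confident
    by convention: no competing placement exists.
    """
    if second_score is None:
        return True
    if top_score < second_score:
        raise ValueError(
            f"localization pair reversed: top {top_score} < second {second_score}"
        )
    return (top_score - second_score) > LOCALIZATION_GAP


@dataclass(frozen=True)
class SiteObservation:
    """One PSM's evidence for a VM site, in protein coordinates."""

    protein: str
    mod_type: str
    n_mods: int
    positions: tuple  # stated (confident) or candidate (ambiguous) set
    confident: bool
    score: float
    peptide_length: int
    spectrum_id: str
    plex_id: str


def _candidate_positions(psm, mod_type, accession, protein_seq, stated):
    """Candidate protein positions for an ambiguous observation."""
    acceptors = MOD_ACCEPTOR_RESIDUES.get(mod_type)
    if acceptors is None:
        return stated
    pep = psm.sequence.upper()
    offset = protein_seq.upper().find(pep)
    positions = {
        offset + i + 1 for i, aa in enumerate(pep) if aa in acceptors
    }
    return tuple(sorted(positions | set(stated)))


def extract_observations(psms, protein_seqs):
    """Turn modified PSMs into per-(PSM, mod_type) site observations.

    Each PSM is mapped through its lexicographically smallest candidate
    protein present in ``protein_seqs``; PSMs without modifications, decoy
    PSMs, and PSMs with no mappable protein are skipped.
    """
    observations = []
    for psm in psms:
        if psm.is_decoy or not psm.modifications:
            continue
        accession = next(
            (a for a in sorted(psm.candidate_proteins) if a in protein_seqs),
            None,
        )
        if accession is None:
            continue
        protein_seq = protein_seqs[accession]
        confident = (
            classify_localization(*psm.localization)
            if psm.localization is not None
            else True
        )
        by_type = {}
        for pos, mod_type in psm.modifications:
            by_type.setdefault(mod_type, []).append((pos, mod_type))
        for mod_type, mods in sorted(by_type.items()):
            sites = map_peptide_to_sites(
                psm.sequence, mods, accession, protein_seq
            )
            stated = tuple(sorted(s.position for s in sites))
            positions = (
                stated
                if confident
                else _candidate_positions(
                    psm, mod_type, accession, protein_seq, stated
                )
            )
            observations.append(
                SiteObservation(
                    accession, mod_type, len(mods), positions, confident,
                    psm.score, len(psm.sequence), psm.spectrum_id, psm.plex_id,
                )
            )
    return observations


def select_representative(members) -> str:
    """Representative spectrum for one site row.

    Confident localization dominates; then higher identification score,
    then longer peptide, then smallest spectrum_id.  Invariant to member
    order.
    """
    if not members:
        raise ValueError("empty member list")
    best = min(
        members,
        key=lambda m: (not m.confident, -m.score, -m.peptide_length,
                       m.spectrum_id),
    )
    return best.spectrum_id


def _make_row(key, members) -> VMSiteRecord:
    protein, mod_type, n_mods, positions, confident = key
    return VMSiteRecord(
        protein=protein,
        positions=positions,
        mod_type=mod_type,
        n_mods=n_mods,
        confident_localized=confident,
        best_score=max(m.score for m in members),
        representative=select_representative(members),
        member_ids=tuple(sorted(m.spectrum_id for m in members)),
        plexes=frozenset(m.plex_id for m in members),
    )


def merge_observations(observations):
    """Merge non-conflicting observations of the same VM site into rows.

    Within each (protein, mod_type, mod count): confident observations
    merge iff their position sets are identical; an ambiguous observation
    joins the confident row whose positions its candidate set contains
    (best-scoring row when several qualify); ambiguous-only clusters are
    keyed by their full candidate set, merging only when equal.
    """
    groups = {}
    for obs in observations:
        groups.setdefault((obs.protein, obs.mod_type, obs.n_mods), []).append(obs)

    rows = []
    for (protein, mod_type, n_mods), members in sorted(groups.items()):
        confident_rows = {}
        ambiguous = []
        for obs in members:
            if obs.confident:
                confident_rows.setdefault(obs.positions, []).append(obs)
            else:
                ambiguous.append(obs)
        leftovers = {}
        for obs in ambiguous:
            candidates = [
                pos
                for pos in confident_rows
                if set(pos) <= set(obs.positions)
            ]
            if candidates:
                # best-scoring confident row wins; positions break ties
                target = max(
                    candidates,
                    key=lambda pos: (
                        max(o.score for o in confident_rows[pos]),
                        tuple(-p for p in pos),
                    ),
                )
                confident_rows[target].append(obs)
            else:
                leftovers.setdefault(obs.positions, []).append(obs)
        for positions in sorted(confident_rows):
            rows.append(
                _make_row((protein, mod_type, n_mods, positions, True),
                          confident_rows[positions])
            )
        for positions in sorted(leftovers):
            rows.append(
                _make_row((protein, mod_type, n_mods, positions, False),
                          leftovers[positions])
            )
    return rows


def build_site_table(psms, protein_seqs):
    """Assemble the VM-site table from modified PSMs.

    Idempotent: rebuilding from a row's own members yields the same row.
    """
    return merge_observations(extract_observations(psms, protein_seqs))


def polish_sites(site_table, min_score: float = 8.0, min_plexes: int = 2):
    """Cross-plex VM-site polishing.

    Retain a site iff its best identification score reaches ``min_score``
    (inclusive) or it was observed in at least ``min_plexes`` plexes —
    removing low-scoring sites seen in only one plex.
    """
    return [
        row
        for row in site_table
        if row.best_score >= min_score or len(row.plexes) >= min_plexes
    ]


def cterm_mod_lysine_filter(peptides):
    """Drop peptides whose last three residues match ``[^K][^K]k``.

    Trypsin/Lys-C cannot cleave C-terminal to a ubiquitylated or
    acetylated lysine (rendered lowercase ``k``), so such peptides are
    artifacts — unless an unmodified K in one of the two preceding
    positions allows a missed cleavage with ambiguous site placement.
    Peptides shorter than three residues are retained.
    """
    return [
        pep
        for pep in peptides
        if len(pep) < 3 or not CTERM_MOD_LYSINE_RE.search(pep)
    ]


def render_modified_sequence(sequence: str, modifications) -> str:
    """Lowercase the K at each modified-lysine position."""
    chars = list(sequence)
    for pos, mod_type in modifications:
        if mod_type in ("acetyl", "diGly") and chars[pos - 1].upper() == "K":
            chars[pos - 1] = "k"
    return "".join(chars)
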