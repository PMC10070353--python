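"""Protein grouping with 'top uses shared' allocation and polishing.

Two proteins sharing a 9-mer form one group; the shared peptide is
allocated to the higher-scoring subgroup.  Within-plex polishing removes
PSMs of subgroups scoring below the best all-decoy-like ('all false')
subgroup, and cross-plex polishing keeps subgroups with score >= 25 or
presence in both plexes.
"""

from psmkit.grouping import (
    build_groups,
    build_peptide_evidence,
    expand_subgroups,
    polish_cross_plex,
)
from psmkit.types import PSMRecord


def make_psm(**overrides):
    fields = dict(
        spectrum_id="S1", run_id="run0", plex_id="plex0", fraction_id="frac0",
        charge=2, precursor_mh=1500.0, mass_error_ppm=0.5, score=12.0,
        delta_rank_score=2.0, delta_fr_score=5.0, bcs=8.0, spi_pct=75.0,
        sequence="ACDEFGHIK",
    )
    fields.update(overrides)
    return PSMRecord(**fields)


def psm(sid, seq, proteins, score, plex="plex0"):
    return make_psm(spectrum_id=sid, sequence=seq,
                    candidate_proteins=proteins, score=score, plex_id=plex)


psms = [
    psm("a", "ACDEFGHIL", ["P"], 20.0),            # unique to P
    psm("b", "MNPQRSTVW", ["Q"], 10.0),            # unique to Q
    psm("c", "ILMNPQRSV", ["P", "Q"], 5.0),        # shared 9-mer
    psm("d", "ACDEFGHIL", ["P"], 15.0),            # lower-scoring duplicate
]
evidence = build_peptide_evidence(psms)
groups = build_groups(evidence)
print("groups:", groups)

for group in groups:
    for sg in expand_subgroups(group, evidence):
        print(f"  subgroup {sg.members}: score {sg.score},"
              f" peptides {sorted(sg.peptides)}")

print()
print("The shared peptide 'ILMNPQRSV' (score 5) went to P's subgroup")
print("(unique score 20 beats Q's 10), so P scores 25 and Q scores 10.")
print("A duplicate spectrum of a peptide counts once, at its best score.")

subgroups = [sg for g in groups for sg in expand_subgroups(g, evidence)]
survivors = polish_cross_plex(subgroups, min_score=25, min_plexes=2)
print(f"\ncross-plex polish (score >= 25 or 2 plexes): "
      f"{[sg.members for sg in survivors]} survive")
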