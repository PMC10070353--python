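"""Assemble a VM-site table: localization, merging, polishing, k-rule.

Three observations of one phosphosite (two charges plus one ambiguous
placement) collapse into a single row; a distinct confident site stays
separate.  Cross-plex polishing then removes low-scoring single-plex
sites, and the C-terminal modified-lysine rule drops tryptic artifacts.
"""

from psmkit.sites import (
    build_site_table,
    classify_localization,
    cterm_mod_lysine_filter,
    polish_sites,
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

PROTEINS = {"P1": "MMASKSATYRLLKSPQRVVSK"}


def obs(sid, mods, loc, score=10.0, plex="plex0", charge=2):
    return make_psm(spectrum_id=sid, sequence="ASKSATY", modifications=mods,
                    localization=loc, score=score, plex_id=plex,
                    charge=charge, candidate_proteins=["P1"])


psms = [
    obs("A", [(2, "phospho")], (10.0, 8.0), charge=2),          # confident S4
    obs("B", [(2, "phospho")], (11.0, 9.0), charge=3),          # same site, z3
    obs("C", [(4, "phospho")], (10.0, 9.5), score=9.0),         # ambiguous
    obs("D", [(6, "phospho")], (12.0, 10.0), score=12.0, plex="plex1"),
]
print("localization gaps:",
      [(p.spectrum_id, classify_localization(*p.localization)) for p in psms])

rows = build_site_table(psms, PROTEINS)
print(f"\n{len(psms)} observations -> {len(rows)} site rows:")
for r in rows:
    print(f"  {r.protein} {r.mod_type}@{r.positions} confident="
          f"{r.confident_localized} best={r.best_score} members={r.member_ids}"
          f" rep={r.representative}")

polished = polish_sites(rows, min_score=8.0, min_plexes=2)
print(f"\nafter polishing (score >= 8 or both plexes): {len(polished)} rows")

peptides = ["AADIDEk", "AAPKk", "LLSDKk", "QQRVk"]
kept = cterm_mod_lysine_filter(peptides)
print(f"\nC-terminal k rule: {peptides} -> kept {kept}")
print("Peptides ending [^K][^K]k are artifacts: trypsin/Lys-C cannot cleave")
print("after a modified lysine unless a missed cleavage explains it.")
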