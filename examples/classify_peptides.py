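"""Tryptic-end classification, protection direction and site mapping.

A semi-tryptic (ST) peptide has one end cut by the limited-proteolysis
protease inside a flexible/accessible region; binding of a bait protects
that region, so ST peptides drop in intensity while fully tryptic (FT)
peptides covering the same region rise.
"""

from lipscreen.hits import map_peptides_to_sites, protection_direction
from lipscreen.report_io import SiteAnnotation, classify_tryptic_type, locate_peptide

protein = "MKAVLRGSTKLLDWAEQRPPVNK"
for peptide in ("AVLR", "VLR", "GSTK", "LLDWAEQR"):
    pos = locate_peptide(protein, peptide)
    tt, flagged = classify_tryptic_type(protein, peptide, pos)
    print(f"{peptide:9s} at {pos}: {tt.value}" + ("  (non-tryptic ends)" if flagged else ""))

print()
for tt, fc in [("ST", -1.2), ("ST", +0.8), ("FT", +1.0), ("FT", -1.0)]:
    print(f"{tt} peptide, log2 FC {fc:+.1f} -> {protection_direction(tt, fc)}")

print()
sites = [SiteAnnotation("P1", "epitope_II", 62, 69)]
for interval in [(62, 75), (80, 95), (200, 210)]:
    call = map_peptides_to_sites(interval, sites, near_window=10)
    print(f"peptide {interval} vs site [62, 69]: {call}")

print("\n'at' means the peptide interval overlaps the annotated interaction")
print("site; 'near' allows a gap of up to near_window residues.")
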