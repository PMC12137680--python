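"""Amine-group counting conventions for short peptides.

The ninhydrin assay sees one colour equivalent per free amine group.
Every peptide keeps its backbone alpha-amine, and ~30 % of residues
(glutamine, arginine, ...) carry a second reactive amine, so intact
peptides can mimic several free amino acids.
"""

from aminogram import classify_peptide, count_amine_groups, enumerate_peptide_count

for seq in ("G", "Q", "GG", "QR", "QGG", "QQQ"):
    n = count_amine_groups(seq)
    cls = classify_peptide(seq)
    print(f"{seq:>4}: {n} amine group(s)  -> class {cls}")

print(f"\ndistinct dipeptides:  {enumerate_peptide_count(2)}")
print(f"distinct tripeptides: {enumerate_peptide_count(3)}")

# A free glutamine reads as 2 amino acids, the tripeptide QQQ as 4 — this
# over-counting is exactly why the before/after-hydrolysis ratio W alone
# cannot separate the species and an averaging estimator is needed.
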