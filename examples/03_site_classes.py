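"""Classify codon degeneracy and build the CNE analysis sets on a toy
chromosome.

A 0-fold site is one where every substitution changes the amino acid;
a 4-fold site tolerates all three. CNE set variants differ in how
exon-overlapping conserved elements are handled.
"""

from popgenpipe.site_classes import (
    SiteClassMap, Transcript, build_cne_flank_reference, build_cne_sets,
    classify_degeneracy,
)

#      0         1
#      0123456789012345
ref = "ATGGGATGTTGGTAA" + "A" * 2000
tr = Transcript("toy", "+", [(0, 15)])
site_map = classify_degeneracy([tr], ref, SiteClassMap.empty(len(ref)))

print("codons: ATG GGA TGT TGG TAA")
for pos in range(15):
    print(f"  pos {pos:2d} ({ref[pos]}): {site_map.class_of(pos)}")

cnes = build_cne_sets([(1000, 1200), (1180, 1300)], [(1250, 1280)],
                      "noOverlap")
print(f"\nCNE noOverlap set (exon at [1250,1280) trimmed): {cnes.intervals}")
flanks = build_cne_flank_reference(cnes, [(1250, 1280)], cnes, len(ref))
print(f"neutral flank reference intervals: {flanks}")
print("(each flank sits 500 bp out and totals half the element length)")
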