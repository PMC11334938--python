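"""Screen genomes for sphingolipid biosynthetic capacity.

Filters serine palmitoyltransferase (Spt) homolog hits (e-value ≤ 1e-70,
query coverage ≥ 70%), checks bCerS/CerR co-localization within 10 ORFs,
and gates Spt candidates by phylogenetic clade: homology alone cannot
separate Spt from other α-oxoamine synthases (Kbl, BioF, HemA).
"""

from sphingolink import (HomologHit, Orf, Tree, colocalized,
                         filter_spt_hits, gate_spt_like, mag_quality, Mag)

hits = [
    HomologHit("spt_q", "scafA_orf010", evalue=1e-95, bitscore=420, qcov=0.88),
    HomologHit("spt_q", "scafB_orf003", evalue=1e-72, bitscore=300, qcov=0.71),
    HomologHit("spt_q", "scafC_orf020", evalue=1e-55, bitscore=180, qcov=0.92),
]
kept = filter_spt_hits(hits)
print("Spt hits kept:", [h.protein_id for h in kept])

spt = Orf("scafA", 10, 8101, 8900, "+", "scafA_orf010")
bcers = Orf("scafA", 15, 12601, 13400, "-", "scafA_orf015")
print("bCerS within 10 ORFs of Spt:", colocalized(spt, bcers))

# references + co-localized homologs form a supported clade (clade B);
# decoy α-oxoamine synthases attach outside and are classified divergent
nwk = ("(((ref_spt_1:1,ref_spt_2:1)99:1,"
       "(scafA_orf010:1,scafB_orf003:1)98:1)99:1,"
       "(kbl_1:1,biof_1:1)90:1);")
tree = Tree.from_newick(nwk, force_rooted=True)
tree.flag_leaves(reference_spt=["ref_spt_1", "ref_spt_2"],
                 colocalized=["scafA_orf010"])
res = gate_spt_like(tree)
print("Spt-like leaves:", sorted(res.spt_like))
print("divergent α-oxoamine synthases:", sorted(res.divergent))

tier, eligible = mag_quality(Mag("MAG1", completeness=80, contamination=2))
print(f"MAG quality: {tier}, association-eligible: {eligible}")
# Only Spt-like proteins inside the gated clade confer producer status;
# the 1e-55 hit and the decoys never reach it.
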