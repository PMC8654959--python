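# Physicochemical group-membership table backing the 31-bit per-residue encoding.
# Format: group-id <TAB> segment <TAB> member residues
#   segment is either "overlap" (one of the 10 overlapping groups, bits 1-10)
#   or "attribute:<name>:<index 1-3>" (the 7 attributes x 3 disjoint groups, bits 11-31).
# Overlapping groups: the Taylor physicochemical classification of the 20
# standard amino acids (aliphatic, aromatic, polar, positive, negative,
# charged, hydrophobic, small, tiny, proline).
# Attributes: the canonical composition/transition/distribution (CTD)
# three-group partitions (Dubchak et al. / PROFEAT tables) for polarity,
# normalized van der Waals volume, hydrophobicity, secondary structure,
# solvent accessibility, charge and polarizability.
aliphatic	overlap	IVL
aromatic	overlap	FYWH
polar	overlap	NQSDECTKRHYW
positive	overlap	KHR
negative	overlap	DE
charged	overlap	KHRDE
hydrophobic	overlap	AGCTIVLKHFYWM
small	overlap	PNDTCAGSV
tiny	overlap	ASGC
proline	overlap	P
polarity.low	attribute:polarity:1	LIFWCMVY
polarity.mid	attribute:polarity:2	PATGS
polarity.high	attribute:polarity:3	HQRKNED
vdw.small	attribute:normalized_vdw_volume:1	GASCTPD
vdw.mid	attribute:normalized_vdw_volume:2	NVEQIL
vdw.large	attribute:normalized_vdw_volume:3	MHKFRYW
hydro.polar	attribute:hydrophobicity:1	RKEDQN
hydro.neutral	attribute:hydrophobicity:2	GASTPHY
hydro.hydrophobic	attribute:hydrophobicity:3	CLVIMFW
ss.helix	attribute:secondary_structure:1	EALMQKRH
ss.strand	attribute:secondary_structure:2	VIYCWFT
ss.coil	attribute:secondary_structure:3	GNPSD
sa.buried	attribute:solvent_accessibility:1	ALFCGIVW
sa.exposed	attribute:solvent_accessibility:2	RKQEND
sa.intermediate	attribute:solvent_accessibility:3	MSPTHY
charge.positive	attribute:charge:1	KR
charge.neutral	attribute:charge:2	ANCQGHILMFPSTWYV
charge.negative	attribute:charge:3	DE
polarizability.low	attribute:polarizability:1	GASDT
polarizability.mid	attribute:polarizability:2	CPNVEQIL
polarizability.high	attribute:polarizability:3	KMHFRYW
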