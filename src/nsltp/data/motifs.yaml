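# Default promoter cis-element definitions, keyed by PLACE identifier
# (Higo et al. 1999, Nucleic Acids Res 27:297; https://www.dna.affrc.go.jp/PLACE).
# Patterns are IUPAC nucleotide strings; scanning is exact-degenerate on both
# strands with overlaps counted and N in the subject never matching.
POLLEN1LELAT52: AGAAA       # late pollen gene lat52 element (S000245)
GTGANTG10: GTGA             # late pollen gene g10 element (S000378)
GT1GMSCAM4: GAAAAA          # soybean calmodulin SCaM-4 GT-1 site (S000453)
CANBNNAPA: CNAACAC          # B. napus napA storage-protein element (S000148)
EBOXBNNAPA: CANNTG          # B. napus napA E-box (S000144)
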