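gene,protein_hgvs,cdna_hgvs,exon,multiplicity
KMT2D,p.Cys247*,c.741T>A,7,2
KMT2D,p.Ser286*,c.855_856del,7,2
KMT2D,p.Gln1773*,c.5317C>T,22,2
KMT2D,p.Gln1949*,c.5845C>T,27,2
KMT2D,p.Gln2109*,c.6325C>T,31,1
KMT2D,p.Arg2645*,c.7933C>T,31,1
KMT2D,p.Arg2801*,c.8401C>T,34,1
KMT2D,p.Gln3910*,c.11728C>T,39,1
KMT2D,p.Gln3942*,c.11824C>T,39,1
KMT2D,p.Gln4223*,c.12667C>T,39,1
KMT2D,p.Gln4230*,c.12688C>T,39,2
KMT2D,p.Arg4484*,c.13450C>T,39,1
KMT2D,p.Arg4904*,c.14710C>T,48,1
KMT2D,p.Arg5282*,c.15844C>T,49,1
KMT2D,p.Tyr5321*,c.15963T>G,50,1
KMT2D,p.Leu656Profs*12,c.1966dup,10,2
KMT2D,p.Glu1224Argfs*26,c.3669dup,11,2
KMT2D,p.Gly1235Valfs*95,c.3699del,11,2
KMT2D,p.Met1379Valfs*52,c.4135_4136del,14,1
KMT2D,p.Asp1876Glyfs*38,c.5627_5630del,25,1
KMT2D,p.Ser2039Glnfs*8,c.6115del,29,2
KMT2D,p.Ala2119Argfs*36,c.6354dup,31,1
KMT2D,p.Pro2330Serfs*47,c.6987_6988insT,31,1
KMT2D,p.Phe3672Leufs*76,c.11016_11019del,39,1
KMT2D,p.Met3894Trpfs*85,c.11679del,39,1
KMT2D,p.Glu4039Glyfs*17,c.12116_12117del,39,1
KMT2D,p.Ser4138Cysfs*29,c.12413_12414del,39,1
KMT2D,p.Leu4483Cysfs*36,c.13446del,39,1
KMT2D,p.Tyr5113Leufs*25,c.15337dup,48,1
KMT2D,p.Lys5139Gly,c.15415_15418del,48,1
KMT2D,p.Leu5318Serfs*14,c.15953_15956del,50,1
KMT2D,,c.674-1G>A,,5
KMT2D,,c.1258+1G>A,,4
KMT2D,,c.2797+1G>C,,4
KMT2D,,c.13531-2A>C,,4
KMT2D,,c.14516-1G>C,,4
KMT2D,p.Ala2182Thr,,10,2
KMT2D,p.Glu1391Lys,c.4171G>A,14,2
KMT2D,p.Arg5048Cys,c.15142C>T,48,2
KMT2D,p.Arg5048His,c.15143G>A,48,2
KMT2D,p.Arg5154Gln,c.15461G>A,48,3
KMT2D,p.Arg5179His,c.15536G>A,48,3
KMT2D,p.Arg5214Cys,c.15640C>T,48,1
KMT2D,p.Gly5295Ala,c.15884G>C,49,1
KMT2D,p.Arg5340Gln,c.16019G>A,50,3
KMT2D,p.Arg5432Trp,c.16294C>T,51,1
KMT2D,p.Val275Ser,c.822_825delinsGTAGGCT,7,1
KDM6A,p.Tyr109*,c.327_333del,3,1
KDM6A,p.Arg172*,c.514C>T,6,1
KDM6A,p.Gln692*,c.2074C>T,17,1
KDM6A,p.Gln1037*,c.3109C>T,20,1
KDM6A,p.Trp1221*,c.3663G>A,25,1
KDM6A,p.Arg1279*,c.3835C>T,26,2
KDM6A,p.Gln607Alafs*25,c.1818_1819del,16,1
KDM6A,p.Thr613Tyrfs*8,c.1846_1849del,16,1
KDM6A,p.Ser1091Metfs*12,c.3270_3273del,17,1
KDM6A,,c.564+1G>T,,1
KDM6A,,c.619+6T>C,,1
KDM6A,,c.620-2A>G,,1
KDM6A,,c.875+1G>A,,1
KDM6A,,c.2939-1G>T,,1
KDM6A,,c.2988+1G>C,,1
KDM6A,,c.3366-8_3366-4del,,1
KDM6A,,deletion of exons 1 and 2,,1
KDM6A,p.Arg481His,c.1442G>A,14,3
KDM6A,p.Arg1255Trp,c.3763C>T,26,2
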