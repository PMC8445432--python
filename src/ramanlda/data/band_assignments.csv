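range_low,range_high,assignment,source_pc
1454,1470,"Nucleic acid content, deoxyribose",PC-2
1421,1429,"Deoxyribose, lipids, DNA, RNA",PC-2
1285,1289,"Cytosine, nucleic acids",PC-6
1122,1135,"Proteins, fatty acids, 1126 cm-1: paraffin",PC-2
1054,1063,"DNA, RNA, lipids","PC-2, PC-6"
999,1003,Phenylalanine,PC-2
985,989,not defined,PC-2
895,933,"Saccharides, collagens, 907 cm-1: formalin",PC-6
706,745,"DNA, RNA, lipids",PC-6
1644,1670,"Amide, nucleic acids",
1428,1456,"Proteins, lipids",
1284,1294,Nucleic acid,
1213,1248,Amide,
1193,1207,Nucleic acids,
1111,1124,"RNA, glucose",
1047,1060,"Lipids, proteins, glycogen",
1030,1030,Phenylalanine,
1003,1003,Phenylalanine,
914,935,"Proteins, collagen",
888,900,"Proteins, saccharides",
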