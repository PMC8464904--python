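# QTAIM bond/ring critical-point properties for the eight oxindole dimers,
# MP2/def2-TZVP, all values in atomic units (printed scaling factors resolved).
# H_printed and ratio_printed are the published derived columns, kept verbatim
# for auditing; the loader re-derives H = G + V and |G/V| itself.
# contact_type: HB = hydrogen-bond-type acceptor contact (N-H...O, C-H...O);
# XB = halogen-involving contact (Br...Br, C-H...Br, C-F...H). cp rows with
# lambda2 > 0 are ring critical points and never enter energy sums.
dimer_id,cp_index,contact,contact_type,rho,lap,H_printed,G,V,ratio_printed,lambda2
1-BrBr,1,Br...Br,XB,0.00637,0.02588,0.001354,0.00512,-0.00376,1.360,-0.00285
2-CHBrBr,1,Br...Br,XB,0.00376,0.01241,0.000744,0.00236,-0.00162,1.460,-0.00193
2-CHBrBr,2,ring,XB,0.00282,0.01098,0.000709,0.00204,-0.00133,1.534,0.00412
2-CHBrBr,3,C-H...Br,XB,0.00481,0.01642,0.000837,0.00327,-0.00243,1.344,-0.00333
1-CHOCHBr,1,C-H...Br,XB,0.00285,0.00980,0.000592,0.00186,-0.00127,1.467,-0.00182
1-CHOCHBr,2,ring,XB,0.00124,0.00471,0.000327,0.00085,-0.00052,1.623,0.00432
1-CHOCHBr,3,C-H...O,HB,0.00738,0.00323,0.001856,0.00622,-0.00437,1.425,-0.00610
2a-CHOCHF,1,C-H...O,HB,0.00777,0.03439,0.001916,0.00668,-0.00477,1.402,-0.00719
2a-CHOCHF,2,ring,XB,0.00158,0.00778,0.000510,0.00143,-0.00925,1.551,0.00652
2a-CHOCHF,3,C-F...H,XB,0.00595,0.02909,0.001701,0.00557,-0.00387,1.440,-0.00551
2b-CHOCHF,1,C-H...O,HB,0.00898,0.03970,0.002248,0.00768,-0.00543,1.414,-0.00893
2b-CHOCHF,2,ring,XB,0.00136,0.00719,0.000510,0.00129,-0.00776,1.657,0.00306
2b-CHOCHF,3,C-F...H,XB,0.00459,0.02154,0.001283,0.00410,-0.00282,1.455,-0.00413
1-NHONHO,1,N-H...O,HB,0.01693,0.11505,0.004763,0.02400,-0.01924,1.248,-0.02125
1-NHONHO,2,ring,HB,0.00265,0.01612,0.000875,0.00315,-0.00228,1.384,0.00579
1-NHONHO,3,N-H...O,HB,0.01693,0.11505,0.004763,0.02400,-0.01924,1.248,-0.02125
2a-NHONHO,1,N-H...O,HB,0.02588,0.12721,0.003898,0.02790,-0.02401,1.162,-0.03626
2a-NHONHO,2,ring,HB,0.00392,0.02332,0.001398,0.00443,-0.00303,1.461,0.00918
2a-NHONHO,3,N-H...O,HB,0.02588,0.12721,0.003898,0.02790,-0.02401,1.162,-0.03626
2b-NHONHO,1,N-H...O,HB,0.02588,0.12721,0.003898,0.02790,-0.02401,1.162,-0.03626
2b-NHONHO,2,ring,HB,0.00392,0.02332,0.001398,0.00443,-0.00303,1.461,0.00918
2b-NHONHO,3,N-H...O,HB,0.02588,0.12721,0.003898,0.02790,-0.02401,1.162,-0.03626
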