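# Published per-dimer energies (MP2/def2-TZVP), kcal/mol. eint_bsse is the
# counterpoise-corrected supramolecular interaction energy; the econt_* columns
# are the published QTAIM contact-energy sums, blank where the source table
# prints a dash (report-layer mask, not a computation rule).
dimer_id,eint_bsse,econt_hb,econt_a,econt_b,econt_c,econt_d
1-BrBr,-0.765,,-1.370,-1.830,-0.885,-1.656
2-CHBrBr,-1.478,,-1.473,-2.013,-0.952,-3.315
1-CHOCHBr,-3.219,-1.768,-2.051,-2.891,-1.326,-3.029
2a-CHOCHF,-2.958,-2.709,-3.143,-4.383,-2.032,-3.151
2b-CHOCHF,-2.999,-2.587,-3.001,-4.212,-1.940,-3.359
1-NHONHO,-10.942,-12.072,,,-9.054,
2a-NHONHO,-11.465,-15.064,,,-11.298,
2b-NHONHO,-11.782,-15.064,,,-11.298,
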