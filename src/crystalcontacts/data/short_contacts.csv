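# Published short intermolecular contacts for structures 1 and 2.
# distance in angstrom; gap = distance minus Bondi vdW radii sum, angstrom.
# NOTE: the published table merges several C-H...Br / C-H...O rows of
# structure 2 against multi-line atom labels; the label/distance pairing below
# is reconstructed by row order and is flagged as such. Only distance and gap
# values enter any numeric test.
structure,contact_class,atom_i,atom_j,elem_i,elem_j,symcode,distance,gap
1,Br...Br,Br1,Br1,Br,Br,"2-x,-y,1-z",3.525,-0.175
1,N-H...O,H1,O1,H,O,"-x,-y,2-z",2.047,-0.673
1,C-H...O,H7,O1,H,O,"-1+x,1/2-y,1/2+z",2.492,-0.228
1,C-H...O,H2B,O1,H,O,"-1+x,y,z",2.691,-0.029
2,N-H...O,H1,O1,H,O,"1-x,1-y,1-z",1.917,-0.803
2,N-H...O,H2,O2,H,O,"-x,1-y,1-z",1.929,-0.791
2,C-H...F,H2A,F2,H,F,"1-x,1/2+y,3/2-z",2.555,-0.115
2,C-H...F,H10B,F1,H,F,"-1-x,3/2-y,-1/2+z",2.646,-0.024
2,C-H...Br,H2A,Br2,H,Br,"x,y,z",2.997,-0.053
2,C-H...Br,H2B,Br1,H,Br,"2-x,-1/2+y,3/2-z",2.979,-0.071
2,C-H...Br,H15,Br1,H,Br,"1-x,-1/2+y,3/2-z",3.006,-0.044
2,C-H...Br,H10A,Br2,H,Br,"x,3/2-y,-1/2+z",2.917,-0.133
2,C-H...O,H5,O2,H,O,"-1-x,3/2-y,-1/2+z",2.419,-0.301
2,C-H...O,H13,O1,H,O,"1-x,1/2+y,3/2-z",2.498,-0.222
2,C-H...O,H2B,O2,H,O,"1-x,1-y,1-z",2.690,-0.030
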