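#helix I 37 62
#helix II 74 98
#helix III 110 132
#helix IV 153 160
#helix V 192 217
#helix VI 346 371
#helix VII 379 403
bead_id	molecule_id	molecule_kind	receptor_id	residue_index	bead_role	helix_label
0	1	receptor	1	48	backbone	I
1	1	receptor	1	164	backbone	IV
2	1	receptor	1	167	backbone	IV
3	1	receptor	1	250	backbone	loop
4	2	receptor	2	48	backbone	I
5	2	receptor	2	164	backbone	IV
6	2	receptor	2	167	backbone	IV
7	3	POPC	-	-	phosphate	-
8	3	POPC	-	-	other	-
9	3	POPC	-	-	other	-
10	4	CHOL	-	-	other	-
11	4	CHOL	-	-	other	-
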