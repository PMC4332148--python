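subunit_name	accession	aliases
α1	PSMA6	alpha1
α2	PSMA2	alpha2
α3	PSMA4	alpha3
α4	PSMA7	alpha4
α5	PSMA5	alpha5
α6	PSMA1	alpha6
α7	PSMA3	alpha7
β1	PSMB6	beta1
β2	PSMB7	beta2
β3	PSMB3	beta3
β4	PSMB2	beta4
β5	PSMB5	beta5
β6	PSMB1	beta6
β7	PSMB4	beta7
β1i	PSMB9	beta1i;LMP2
β2i	PSMB10	beta2i;MECL1
β5i	PSMB8	beta5i;LMP7
Rpt1	PSMC2	rpt1
Rpt2	PSMC1	rpt2
Rpt3	PSMC4	rpt3
Rpt4	PSMC6	rpt4
Rpt5	PSMC3	rpt5
Rpt6	PSMC5	rpt6
Rpn1	PSMD2	rpn1
Rpn2	PSMD1	rpn2
Rpn3	PSMD3	rpn3
Rpn5	PSMD12	rpn5
Rpn6	PSMD11	rpn6
Rpn7	PSMD6	rpn7
Rpn8	PSMD7	rpn8
Rpn9	PSMD13	rpn9
Rpn10	PSMD4	rpn10
Rpn11	PSMD14	rpn11
Rpn12	PSMD8	rpn12
Rpn13	ADRM1	rpn13
Rpn14	PAAF1	rpn14
PA28α	PSME1	PA28alpha;REGalpha
PA28β	PSME2	PA28beta;REGbeta
PA28γ	PSME3	PA28gamma;REGgamma;Ki antigen
PA200	PSME4	pa200
PI31	PSMF1	pi31
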