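complex_name	aggregation	members
ncP20S	median	α1;α2;α3;α4;α5;α6;α7;β3;β4;β6;β7
19S	median	Rpt1;Rpt2;Rpt3;Rpt4;Rpt5;Rpt6;Rpn1;Rpn2;Rpn3;Rpn5;Rpn6;Rpn7;Rpn8;Rpn9;Rpn10;Rpn11;Rpn12;Rpn13;Rpn14
PA28αβ	median	PA28α;PA28β
sP20S	single	β5
iP20S	single	β2i
PA28γ	single	PA28γ
PA200	single	PA200
PI31	single	PI31
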