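study_id,condition_label,country,s_zero,s_half,s_all,prosocial_rate,n_participants
Antinyan et al.,control,Armenia,3.20,5.50,4.75,,
Antinyan et al.,loss manipulation 1,Armenia,3.50,5.50,4.50,,
Antinyan et al.,loss manipulation 2,Armenia,2.50,5.00,4.00,,
Brañas-Garza,baseline,Spain,2.50,5.50,4.50,,
Brañas-Garza,helping others,Spain,2.00,6.00,5.00,,
Brañas-Garza,reciprocity,Spain,2.50,6.50,4.50,,
Bruttel & Stolley,control,Germany,3.00,5.50,4.50,,
Bruttel & Stolley,decision power condition,Germany,2.50,5.50,4.50,,
Bruttel & Stolley,responsibility condition,Germany,2.50,5.50,4.50,,
Capraro & Vanzo,boost condition,USA,3.25,,5.75,,
Capraro & Vanzo,demand condition,USA,2.25,,5.75,,
Capraro & Vanzo,donate condition,USA,3.25,,5.75,,
Capraro & Vanzo,give condition,USA,2.75,,5.75,,
Capraro & Vanzo,steal condition,USA,1.50,,6.50,,
Capraro & Vanzo,take condition,USA,2.25,,5.75,,
Dreber et al.,Exp 1 - giving informed,USA,2.15,5.40,6.20,,
Dreber et al.,Exp 1 - giving uninformed,USA,2.50,5.75,6.25,,
Dreber et al.,Exp 1 - taking informed,USA,1.50,2.50,6.00,,
Dreber et al.,Exp 1 - taking uninformed,USA,1.75,4.25,6.50,,
Dreber et al.,Exp 2 - giving give,USA,2.50,5.25,6.75,,
Dreber et al.,Exp 2 - giving transfer,USA,2.50,5.25,6.25,,
Dreber et al.,Exp 2 - keeping keep,USA,2.45,4.50,6.25,,
Dreber et al.,Exp 2 - keeping transfer,USA,2.50,5.00,6.00,,
Dreber et al.,Exp 3 - giving Informed,USA,2.15,5.45,6.50,,
Dreber et al.,Exp 3 - giving uninformed,USA,2.50,5.00,6.50,,
Dreber et al.,Exp 3 - taking informed,USA,2.50,4.00,6.50,,
Dreber et al.,Exp 3 - taking uninformed,USA,2.15,3.65,6.20,,
Herne et al.,baseline,Finland,2.50,5.50,5.00,,
Herne et al.,certainty empathy,Finland,2.00,5.80,4.80,,
Herne et al.,uncertainty empathy,Finland,2.50,6.00,5.00,,
Herne et al.,uncertainty no empathy,Finland,2.20,5.80,4.40,,
Kettner & Ceccato,give female,Germany,4.50,6.00,5.50,,
Kettner & Ceccato,give male,Germany,4.50,6.00,5.25,,
Kettner & Ceccato,take female,Germany,2.00,3.50,5.50,,
Kettner & Ceccato,take male,Germany,2.50,3.50,5.50,,
Kettner & Waichman,give hypothetical,Germany,4.50,5.50,5.50,,
Kettner & Waichman,give incentivized,Germany,4.00,5.50,5.00,,
Kettner & Waichman,take hypothetical,Germany,2.00,2.50,6.00,,
Kettner & Waichman,take incentivized,Germany,2.00,2.50,5.50,,
Kuang & Bicchieri,control,USA,2.75,5.50,6.50,,
Kuang & Bicchieri,"ind. injunction, appropriate",USA,3.25,5.50,6.75,,
Kuang & Bicchieri,"ind. injunction, approved",USA,2.50,5.50,6.50,,
Kuang & Bicchieri,"ind. injunction, desirable",USA,2.50,6.00,6.50,,
Kuang & Bicchieri,"ind. injunction, okay",USA,3.25,5.75,6.50,,
Kuang & Bicchieri,"ind. injunction, permissible",USA,3.50,5.50,6.50,,
Kuang & Bicchieri,"ind. injunction, should",USA,2.30,5.20,6.75,,
Kuang & Bicchieri,"ind. injunction, the right thing",USA,2.75,5.50,6.50,,
Ockenfels & Werner,info condition 1,Germany,2.50,5.50,4.50,,
Ockenfels & Werner,info condition 2,Germany,2.50,5.50,4.50,,
Ockenfels & Werner,noInfo condition 1,Germany,2.50,5.50,4.00,,
Ockenfels & Werner,noInfo condition 2,Germany,2.50,5.50,4.50,,
Schurter & Wilson,die roll condition,USA,2.50,6.50,4.50,,
Schurter & Wilson,quiz condition,USA,2.50,6.00,2.50,,
Schurter & Wilson,seniority condition,USA,2.35,6.45,4.20,,
Schurter & Wilson,unannounced condition,USA,2.45,6.10,2.75,,
Walkowitz,DeRo25,Germany,2.50,5.50,4.50,,
Walkowitz,Dec50,Germany,2.25,5.75,4.75,,
Walkowitz,N-N,Germany,2.00,5.00,4.00,,
Walkowitz,N-N-2,Germany,2.50,4.50,5.50,,
Walkowitz,Pay50,Germany,2.50,5.50,4.50,,
Walkowitz,Rol50,Germany,2.50,5.50,4.50,,
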