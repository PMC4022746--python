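sport,sex,n_common,n_weight_height,n_skinfold_circumference,n_dxa
archery_shooting,female,0,4,4,0
archery_shooting,male,0,9,9,0
athletics,female,9,32,25,16
athletics,male,4,30,23,11
basketball,female,31,43,39,34
basketball,male,44,47,46,45
fencing,female,0,4,4,0
fencing,male,0,12,12,0
gymnastics,female,12,18,18,12
gymnastics,male,2,20,20,2
handball,female,4,4,4,4
handball,male,20,37,20,37
hockey_rink,female,0,0,0,0
hockey_rink,male,1,49,48,2
korfball,female,0,9,9,0
korfball,male,0,11,11,0
modern_pentathlon,female,1,9,8,2
modern_pentathlon,male,5,14,14,5
motorsport,female,0,0,0,0
motorsport,male,0,7,7,0
other_combat,female,0,15,11,4
other_combat,male,8,34,29,13
rowing,female,1,8,8,1
rowing,male,6,27,27,6
rugby,female,0,0,0,0
rugby,male,39,62,62,39
sailing,female,0,7,7,0
sailing,male,3,38,37,4
soccer,female,0,22,22,0
soccer,male,3,42,17,28
surf,female,1,1,1,1
surf,male,0,1,1,0
swimming,female,22,26,26,22
swimming,male,34,44,42,36
tennis,female,4,11,10,5
tennis,male,7,23,19,11
triathlon,female,6,11,8,10
triathlon,male,30,41,33,38
volleyball,female,16,16,16,16
volleyball,male,17,17,17,17
wrestling_judo,female,12,24,21,15
wrestling_judo,male,39,69,64,45
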