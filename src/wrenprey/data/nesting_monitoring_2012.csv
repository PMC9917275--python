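site,territory,first_egg_julian,nest_attempts,successful_clutches,total_eggs,fledglings,mortality_note
BC,BC:2,100,2,2,7,7,none
BC,BC:4,106,2,1,5,1,3 nestlings depredated; 1 unhatched egg
BC,BC:5,123,1,1,4,3,"nestling mortality, cause unknown"
SCR,SCR:1,130,2,0,7,0,both nests failed in early nestling stage
SCR,SCR:5,106,1,1,2,2,none
UCI,UCI:3,75,1,0,4,0,"adult bird depredated, nestlings die"
UCI,UCI:6,104,2,1,7,3,1st nest failed; 1 nestling depredated in 2nd
UCI,UCI:9,52,4,3,15,6,2nd nest failed in early nestling stage
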