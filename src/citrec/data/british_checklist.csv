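informalGroup,britishSpeciesTotal
terrestrial mammal,64
bird,587
beetle,4079
dragonfly,59
butterfly,64
moth,2323
true bug,604
spider,689
fungus,13517
flowering plant,4900
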