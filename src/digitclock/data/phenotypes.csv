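species,limb,digit,phalanx_min,phalanx_max,claw,present,provisional
ancestor,forelimb,1,2,2,1,1,0
ancestor,forelimb,2,3,3,1,1,0
ancestor,forelimb,3,4,4,1,1,0
ancestor,forelimb,4,5,5,1,1,0
ancestor,forelimb,5,3,3,1,1,0
ancestor,hindlimb,1,2,2,1,1,0
ancestor,hindlimb,2,3,3,1,1,0
ancestor,hindlimb,3,4,4,1,1,0
ancestor,hindlimb,4,5,5,1,1,0
ancestor,hindlimb,5,4,4,1,1,0
bearded_dragon,forelimb,1,2,2,1,1,0
bearded_dragon,forelimb,2,3,3,1,1,0
bearded_dragon,forelimb,3,4,4,1,1,0
bearded_dragon,forelimb,4,5,5,1,1,0
bearded_dragon,forelimb,5,3,3,1,1,0
bearded_dragon,hindlimb,1,2,2,1,1,0
bearded_dragon,hindlimb,2,3,3,1,1,0
bearded_dragon,hindlimb,3,4,4,1,1,0
bearded_dragon,hindlimb,4,5,5,1,1,0
bearded_dragon,hindlimb,5,4,4,1,1,0
tokay_gecko,forelimb,1,2,2,1,1,0
tokay_gecko,forelimb,2,3,3,1,1,0
tokay_gecko,forelimb,3,4,4,1,1,0
tokay_gecko,forelimb,4,5,5,1,1,0
tokay_gecko,forelimb,5,3,3,1,1,0
tokay_gecko,hindlimb,1,2,2,1,1,0
tokay_gecko,hindlimb,2,3,3,1,1,0
tokay_gecko,hindlimb,3,4,4,1,1,0
tokay_gecko,hindlimb,4,5,5,1,1,0
tokay_gecko,hindlimb,5,4,4,1,1,0
mouse,forelimb,1,2,2,1,1,0
mouse,forelimb,2,3,3,1,1,0
mouse,forelimb,3,3,3,1,1,0
mouse,forelimb,4,3,3,1,1,0
mouse,forelimb,5,3,3,1,1,0
mouse,hindlimb,1,2,2,1,1,0
mouse,hindlimb,2,3,3,1,1,0
mouse,hindlimb,3,3,3,1,1,0
mouse,hindlimb,4,3,3,1,1,0
mouse,hindlimb,5,3,3,1,1,0
chinese_softshell_turtle,forelimb,1,2,2,1,1,0
chinese_softshell_turtle,forelimb,2,3,3,1,1,0
chinese_softshell_turtle,forelimb,3,3,3,1,1,0
chinese_softshell_turtle,forelimb,4,3,6,0,1,0
chinese_softshell_turtle,forelimb,5,2,5,0,1,0
chinese_softshell_turtle,hindlimb,1,2,2,1,1,0
chinese_softshell_turtle,hindlimb,2,3,3,1,1,0
chinese_softshell_turtle,hindlimb,3,3,3,1,1,0
chinese_softshell_turtle,hindlimb,4,3,6,0,1,0
chinese_softshell_turtle,hindlimb,5,2,5,0,1,0
caiman,forelimb,1,2,2,1,1,0
caiman,forelimb,2,3,3,1,1,0
caiman,forelimb,3,4,4,1,1,0
caiman,forelimb,4,5,5,0,1,0
caiman,forelimb,5,3,3,0,1,0
caiman,hindlimb,1,2,2,1,1,0
caiman,hindlimb,2,3,3,1,1,0
caiman,hindlimb,3,4,4,1,1,0
caiman,hindlimb,4,5,5,0,1,0
caiman,hindlimb,5,0,0,0,0,0
dwarf_crocodile,forelimb,1,2,2,1,1,0
dwarf_crocodile,forelimb,2,3,3,1,1,0
dwarf_crocodile,forelimb,3,4,4,1,1,0
dwarf_crocodile,forelimb,4,5,5,0,1,0
dwarf_crocodile,forelimb,5,3,3,0,1,0
dwarf_crocodile,hindlimb,1,2,2,1,1,0
dwarf_crocodile,hindlimb,2,3,3,1,1,0
dwarf_crocodile,hindlimb,3,4,4,1,1,0
dwarf_crocodile,hindlimb,4,5,5,0,1,0
dwarf_crocodile,hindlimb,5,0,0,0,0,0
nile_crocodile,forelimb,1,2,2,1,1,0
nile_crocodile,forelimb,2,3,3,1,1,0
nile_crocodile,forelimb,3,4,4,1,1,0
nile_crocodile,forelimb,4,5,5,0,1,0
nile_crocodile,forelimb,5,3,3,0,1,0
nile_crocodile,hindlimb,1,2,2,1,1,0
nile_crocodile,hindlimb,2,3,3,1,1,0
nile_crocodile,hindlimb,3,4,4,1,1,0
nile_crocodile,hindlimb,4,5,5,0,1,0
nile_crocodile,hindlimb,5,0,0,0,0,0
rhea,forelimb,1,0,0,0,0,0
rhea,forelimb,2,2,2,1,1,0
rhea,forelimb,3,2,2,0,1,0
rhea,forelimb,4,1,1,0,1,1
rhea,forelimb,5,0,0,0,0,0
rhea,hindlimb,1,0,0,0,0,0
rhea,hindlimb,2,3,3,1,1,0
rhea,hindlimb,3,4,4,1,1,0
rhea,hindlimb,4,5,5,1,1,0
rhea,hindlimb,5,0,0,0,0,0
ostrich,forelimb,1,0,0,0,0,1
ostrich,forelimb,2,2,2,1,1,1
ostrich,forelimb,3,2,2,0,1,1
ostrich,forelimb,4,1,1,0,1,1
ostrich,forelimb,5,0,0,0,0,1
ostrich,hindlimb,1,0,0,0,0,1
ostrich,hindlimb,2,3,3,1,1,1
ostrich,hindlimb,3,4,4,1,1,1
ostrich,hindlimb,4,5,5,1,1,1
ostrich,hindlimb,5,0,0,0,0,1
emu,forelimb,1,0,0,0,0,1
emu,forelimb,2,2,2,1,1,1
emu,forelimb,3,2,2,0,1,1
emu,forelimb,4,1,1,0,1,1
emu,forelimb,5,0,0,0,0,1
emu,hindlimb,1,0,0,0,0,1
emu,hindlimb,2,3,3,1,1,1
emu,hindlimb,3,4,4,1,1,1
emu,hindlimb,4,5,5,1,1,1
emu,hindlimb,5,0,0,0,0,1
duck,forelimb,1,0,0,0,0,0
duck,forelimb,2,2,2,1,1,0
duck,forelimb,3,3,3,1,1,0
duck,forelimb,4,2,2,0,1,0
duck,forelimb,5,0,0,0,0,0
duck,hindlimb,1,2,2,1,1,0
duck,hindlimb,2,3,3,1,1,0
duck,hindlimb,3,4,4,1,1,0
duck,hindlimb,4,5,5,1,1,0
duck,hindlimb,5,0,0,0,0,0
chicken,forelimb,1,0,0,0,0,0
chicken,forelimb,2,2,2,1,1,0
chicken,forelimb,3,2,2,0,1,0
chicken,forelimb,4,2,2,0,1,0
chicken,forelimb,5,0,0,0,0,0
chicken,hindlimb,1,2,2,1,1,0
chicken,hindlimb,2,3,3,1,1,0
chicken,hindlimb,3,4,4,1,1,0
chicken,hindlimb,4,5,5,1,1,0
chicken,hindlimb,5,0,0,0,0,0
zebra_finch,forelimb,1,0,0,0,0,0
zebra_finch,forelimb,2,1,1,0,1,1
zebra_finch,forelimb,3,2,2,0,1,1
zebra_finch,forelimb,4,1,1,0,1,1
zebra_finch,forelimb,5,0,0,0,0,0
zebra_finch,hindlimb,1,2,2,1,1,0
zebra_finch,hindlimb,2,3,3,1,1,0
zebra_finch,hindlimb,3,4,4,1,1,0
zebra_finch,hindlimb,4,5,5,1,1,0
zebra_finch,hindlimb,5,0,0,0,0,0
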