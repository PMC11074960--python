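Washington	Augustine	0	0	1
Washington	AugustineWife	0	0	2
Washington	SamuelWife	0	0	2
Washington	JohnAugustineWife	0	0	2
Washington	LucyPayne	0	0	2
Washington	BurialBWife	0	0	2
Washington	JA2Wife	0	0	2
Washington	JA3Wife	0	0	2
Washington	SWWGrandmother	0	0	2
Washington	SWWMother	0	0	2
Washington	Samuel	Augustine	AugustineWife	1
Washington	JohnAugustine	Augustine	AugustineWife	1
Washington	GeorgeSteptoeSr	Samuel	SamuelWife	1
Washington	Burial3	GeorgeSteptoeSr	LucyPayne	1
Washington	BurialB	GeorgeSteptoeSr	LucyPayne	1
Washington	ChristianMaria	BurialB	BurialBWife	2
Washington	JA2	JohnAugustine	JohnAugustineWife	1
Washington	JA3	JA2	JA2Wife	1
Washington	RichardScottBlackburn	JA3	JA3Wife	1
Washington	SWWGrandfather	RichardScottBlackburn	ChristianMaria	1
Washington	SWWFather	SWWGrandfather	SWWGrandmother	1
Washington	SWW	SWWFather	SWWMother	1
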