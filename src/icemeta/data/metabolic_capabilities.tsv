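process	basal	accretion
Nitrogen fixation (N2 -> NH4+)	Ac, Fi, αP, βP	Ac, Cy, Fi, αP, βP, εP, γP
Nitrification (NH4+ -> NO2-)	βP	αP, βP
Nitrification (NO2- -> NO3-)	Ac	αP, βP
Denitrification (NO2- -> NH4+)	Ac, DT, αP, βP, δP, γP	Fi, αP, βP, γP
Denitrification (NO3- -> NO2-)	Ac	Fi, αP, βP, γP
Denitrification (NO3- -> N2)	Ac, DT, αP, βP, δP, γP	Fi, αP, βP, γP
Nitrate reduction (NO3- -> NH4+)	δP, γP	Fi, αP, βP, γP
Assimilation (NH4+ -> organic)	many	many
Decomposition (organic -> NH4+)	Ac, γP, As, Bd, other heterotrophs	As, Bd, other heterotrophs
Anammox (NH4+ + NO2- -> N2)	Pl	Pl
Carbon fixation: reductive pentose phosphate	Ad, Ch, Cy, αP, βP, γP	Cy, αP, βP, γP
Carbon fixation: reductive TCA	Cb	Cb, αP, δP, εP
Carbon fixation: reductive acetyl-CoA	Ar	Ar
Carbon fixation: 3-hydroxypropionate bicycle	αP	Cb
C-1 metabolism	αP, βP	αP, βP
Arsenic oxidation	αP	βP
Arsenate reduction	αP	βP
Chromium reduction	Ac, αP, βP	nd
Iron oxidation	βP	βP
Iron reduction	αP, βP, δP	δP
Manganese oxidation	nd	δP
Methylotrophy	αP, βP	βP, As
Sulfur oxidation	βP, γP	βP
Sulfate reduction	βP, δP	δP
Uranium oxidation	Fi, βP	nd
Uranium reduction	Fi, δP	nd
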