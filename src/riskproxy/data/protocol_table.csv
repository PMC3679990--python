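name,risk,lineage,age_range,wbc_range,genetics,other
AALL02P2,HR,T,>=10 (or),>=50 (or),,
AALL0031,HR,,,,t(9;22) or hypodiploidy or MLL with slow response (or),Induction failure (or)
AALL0232,HR,B,>=10 (or),>=50 (or),,Steroid pre treatment (or)
AALL0331,SR,B,1-9,<50,,
AALL0434,HR,T,>1,,,
AALL0622,HR,,>1,,t(9;22),
AALL0631,HR,,<1,,,
AALL0932,SR,B,1-9,<50,"No t(9;22), MLL, iAMP21, hypodiploidy",
CCG1991,SR,B,1-9,<50,,
POG9201,SR,B,1-9,<50,"Trisomy 4,10, DI>1.16 or t(12;21); No t(9;22), 1;19, MLL",
POG9407,HR,,<1,,,
POG9605,SR,B,1-9 / >=10 / >1,<50 / <50 / >=50,"No trisomy 4,10, DI>1.16, MLL, t(1;19), t(9;22) (first arm); Trisomy 4,10 or DI>1.16 arms",
POG9904,SR,B,1-9,<50,"Trisomy 4,10, DI>1.16 or t(12;21); No MLL, t(1;19), t(9;22)",
POG9905,SR,,,,,"Neither 9904, 9906 nor AALL0031"
POG9906,HR,B,M>12; F>16 (or),>100 (or),MLL (or),Sliding scale of WBC criteria for M age 8-11 and F age 12-15
PROTOCOL C,HR,,<1 or >10 (or),>20 (or),t(9;22) or MLL (or),"L2 morphology, mediastinal mass, or massive LN/HSM"
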