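schemeId,nationalLabel,iucnCode
default,EX,EX
default,EW,EW
default,RE,EX
default,CR,CR
default,EN,EN
default,VU,VU
default,NT,NT
default,LC,LC
default,DD,DD
default,NE,NE
default,Extinct,EX
default,Regionally Extinct,EX
default,Extinct in the Wild,EW
default,Critically Endangered,CR
default,Endangered,EN
default,Vulnerable,VU
default,Near Threatened,NT
default,Least Concern,LC
default,Data Deficient,DD
default,Not Evaluated,NE
default,Ausgestorben,EX
default,Vom Aussterben bedroht,CR
default,Stark gefährdet,EN
default,Gefährdet,VU
default,Vorwarnliste,NT
default,Ungefährdet,LC
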