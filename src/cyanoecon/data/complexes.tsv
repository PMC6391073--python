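name	formula
Elongation factor	TufA
Phosphoglycerate kinase	Pgk
Ribosome small subunit	Rps1A,1B,B,C,D,E,F,G,H,I,J,K,L,M,N,O,P,Q,R,S,T,U
Phycobilisome (phycocyanin)	((CpcA,B)18,C1,C2,D,G)6
Photosystem I	(PsaA,B,C,D,E,F,I,J,K,L,M,X)3
Ribosome large subunit	RplA,B,C,D,E,F,I,J,K,L,M,N,O,P,Q,R,S,T,U,V,W,X,Y,RpmA,B,C,E,F,G,H,I,J
Transketolase	TktA2
PII signal transducing protein	GlnB3
Photosystem II	(PsbA1,A2,B,C,D,E,F,H,I,J,K,L,M,N,O,T,U,V,X,Y,Z,Ycf12)2
RuBisCO	(RbcL,RbcS)8
Ferredoxin-NADP reductase (FNR)	PetH
D-fructose 1,6-bisphosphatase class 2	Slr20944
Phycobilisome (allophycocyanin)	(ApcA,B)34,C6,D2,E6,F2
G3P dehydrogenase	Gap2*4
Plastocyanin	PetE
Superoxide dismutase [Fe]	SodB2
Orange carotenoid protein	Slr19632
RNA polymerase	RpoA*2,RpoB,RpoC1*1,RpoC2*1,RpoD,RpoE,RpoF
Chaperonine GroEL	GroL1*14
Ribosome recycling factor	Frr
Phosphoglycerate dehydrogenase	SerA4
Pyruvate dehydrogenase	(PdhA,PdhB)2
Glutamine synthetase	GlnA*12
Isocitrate dehydrogenase	Icd2
Glycogen synthase	GlgA*1
DNA polymerase III	DnaN2
Pyruvate kinase	Pyk2*4
Acetyl-coenzyme A carboxylase	AccB,AccC,AccA2,AccD2
Carbonic anhydrase	IcfA6
Acetyl-coenzyme A reductase	PhaB4
Circadian clock KaiA	KaiA2
Circadian clock KaiB	KaiB4
Circadian clock KaiC	KaiC6
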