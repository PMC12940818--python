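captopril	Capoten
captopril	SQ-14225
enalapril	Vasotec
enalapril	MK-421
enalapril	enalapril maleate
lisinopril	Prinivil
lisinopril	Zestril
enalaprilat	MK-422
cilazapril	Inhibace
benazepril	Lotensin
fosinopril	Monopril
quinapril	Accupril
ramipril	Altace
delapril	Adecut
racecadotril	acetorphan
perindopril	Coversyl
perindopril	Aceon
spirapril	Renormax
moexipril	Univasc
trandolapril	Mavik
zofenopril	Zofenil
alacepril	Cetapril
imidapril	Tanatril
temocapril	Acecol
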