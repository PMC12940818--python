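# Sentence-boundary guard list: a period ending one of these does not end a sentence.
e.g.
i.e.
vs.
et al.
al.
Fig.
Figs.
Tab.
Ref.
No.
approx.
ca.
cf.
Dr.
Prof.
St.
spp.
sp.
subsp.
wt.
vol.
resp.
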