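host,BSLT,La Perla,Caleria,total
Dioe,44,33,0,77
Xaro,18,0,0,18
Rhwe,17,2,0,19
Phin,0,0,9,9
Phra,18,0,0,18
Phsa,7,38,0,45
Phse,1,6,4,11
Phtr,18,15,20,53
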