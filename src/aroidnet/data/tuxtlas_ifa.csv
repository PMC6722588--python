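host,n_units,species,rf,ra,ifa
Dioe,73,B.tux,0.932,0.752,70.01
Dioe,73,Dro,0.562,0.225,12.66
Xaro,19,Nit1,0.789,0.541,42.72
Xaro,19,B.pal,0.737,0.182,13.45
Phsa,38,Sym,0.447,0.585,26.15
Phsa,38,Nit1,0.342,0.202,6.89
Phin,9,Psec,1.00,0.462,46.21
Phin,9,Mer4,0.667,0.14,9.36
Phse,8,Nit1,0.875,0.285,24.92
Phse,8,Psec,0.25,0.585,14.63
Phra,18,Apr,0.444,0.732,32.52
Phra,18,Sym,0.833,0.22,18.33
Phtr,41,Mer2,0.537,0.168,9.04
Phtr,41,Neo,0.22,0.313,6.88
Rhwe,9,Sep,0.889,0.995,88.4
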