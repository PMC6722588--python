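family,species,code,guild,Dioe,Phin,Phra,Phsa,Phse,Phtr,Rhwe,Xaro,total
Curculionidae,Curculionidae-2,Cur2,P,0,0,0,0.04,0,0.13,0,0,2
Nitidulidae,Nitidulidae-1,Nit1,P-S,0,8.68,0.04,20.15,28.48,9.33,0,54.14,1781
Nitidulidae,Nitidulidae-2,Nit2,P-S,0,0,0.14,0,0,0,0,0.05,12
Nitidulidae,Nitidulidae-3,Nit3,P-S,0,0,0,0,0,0,0,2.79,57
Nitidulidae,Nitidulidae-5,Nit5,P-S,0,0,0,0.18,0,0,0,0,4
Ptiliidae,Ptiliidae,Pti,M,0,0,0,1.15,9.6,0,0,0,57
Scarabaeidae,Cyclocephala sexpunctata,C.sex,P,0,0,0,0,0,0,0,0.05,1
Agromyzidae,Agromyzidae-1,Agr,P,0,0.16,0,0,0,0,0,0,1
Cecidomyiidae,Cecidomyiidae-1,Cec1,P,0,0.16,0,0,0,0.65,0,0,6
Cecidomyiidae,Cecidomyiidae-2,Cec2,P,0,0,0,0.13,0,0,0,0,3
Ceratopogonidae,Ceratopogonidae-1,Cer1,P,0,0.16,0,0,0,0,0,0,1
Ceratopogonidae,Forcipomyia sp.,For,P,0,0,0.23,0,0,3.5,0,0.05,46
Chloropidae,Chloropidae-1,Chl1,P,0,0,0,0,0,0,0,0.69,14
Chloropidae,Chloropidae-2,Chl2,P,0,0,0,0,0,0,0,0.49,10
Drosophilidae,Drosophilidae-spp.,Dro,P-S,22.53,8.36,0.24,0.04,0,0.13,0.55,0.34,445
Lonchaeidae,Neosilba sp.,Neo,P-S,0.06,1.89,0,4.39,1.55,31.35,0,0,359
Muscidae,Potamia sp.,Pot,S,0,8.83,0.03,0.36,0,0.13,0,0,67
Neriidae,Glyphidops sp.,Gly,S,0,0,0.01,0,0,0,0,0,1
Psychodidae,Psychodidae-spp.,Psyc,P-S,0.06,0,0.36,0,0,0.65,0,2.35,83
Richardiidae,Beebeomyia palposa,B.pal,P,0,0,0,0,0,0,0,18.23,372
Richardiidae,Beebeomyia sp3,B.sp3,P,0,0,3.41,8.43,0,6.87,0,0,514
Richardiidae,Beebeomyia tuxtlaensis,B.tux,P,75.16,0,0,0,0,0,0,0,1204
Richardiidae,Sepsisoma sp.,Sep,P,0,0,0,0,0,0,99.45,0,543
Scatopsidae,Psectrosciara sp.,Psec,P,0.25,46.21,0,0.58,58.51,1.55,0,0,511
Sciaridae,Sciaridae-spp,Sci,M,0.37,0,0.06,0,0,4.92,0,12.49,304
Stratiomyidae,Merosargus-1,Mer1,P,0.19,8.04,0.16,0.71,0,3.37,0,5.68,225
Stratiomyidae,Merosargus-2,Mer2,P,0.31,0,0,0,0,16.84,0,1.27,162
Stratiomyidae,Merosargus-3,Mer3,P,0.06,0,0.01,5.37,0,1.81,0,0,137
Stratiomyidae,Merosargus-4,Mer4,P,0,14.04,0,0,1.86,1.04,0,0,102
Syrphidae,Copestylum sp.,Cop,P-S,0,0,0.01,0,0,0.52,0,0,5
Tipulidae,Rhipidia sp.,Rhi,P,1,0,0.09,0,0,1.68,0,0.93,55
Tipulidae,Symplecta sp.,Sym,P,0,3.47,21.99,58.46,0,15.54,0,0.44,3216
Eulophidae,Aprostocetus sp.,Apr,P,0,0,73.17,0,0,0,0,0,5816
Pyralidae,Pyralidae,Pyr,P,0,0,0.05,0,0,0,0,0,4
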