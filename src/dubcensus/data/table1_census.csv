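dub,uniprot,subfamily,domains,localization,interactors,ortholog_sc,ortholog_hs,complex_conserved_sc,complex_conserved_hs
Ubp1,Q9USM5,USP,USP;DUSP,CS(ER),,Ubp12p,NA,0,0
Ubp2,Q9P3U0,USP,USP,C,Ucp6,Ubp2p,NA,1,0
Ubp3,O94269,USP,USP,C,Nxt3,Ubp3p,USP10,1,1
Ubp4,O60139,USP,USP,CS(endosomes),Sfp47,Doa4p/Ubp5p,USP8,0,0
Ubp5,Q09879,USP,USP;MATH,CS(Golgi),Ftp105,Ubp15p,USP7,0,0
Ubp6,Q92353,USP,USP;UBL,N,26S proteasome,Ubp6p,USP14,1,1
Ubp7,Q9P7S5,USP,USP,C,,Ubp11p,USP45,0,0
Ubp8,Q09738,USP,USP;ZnF-UBP,N,SAGA subunits,Ubp8p,USP22,1,1
Ubp9,Q9P7V9,USP,USP,N|CS(cell tips/septum),Bun62;Bun107,Ubp9p/Ubp13p,USP12/USP46,1,1
Ubp11,Q9UUD6,USP,USP,M,Tom70,NA,NA,0,0
Ubp12,O60079,USP,USP;DUSP,N|C,,Ubp12p,USP4/USP15,0,0
Ubp14,Q11119,USP,USP;ZnF-UBP;UBA,N,,Ubp14p,USP5,0,0
Ubp15,Q9UTT1,USP,USP;MATH,N|CS,,Ubp15p,USP7,0,0
Ubp16,O74442,USP,USP,No,,Ubp10p,NA,0,0
Uch1,Q10171,UCH,UCH,N|C,,Yuh1p,UCHL3,0,0
Uch2,Q9UUB6,UCH,UCH,NE,26S proteasome,NA,UCHL5,0,1
Otu1,O13974,OTU,OTU,N|C,Cdc48,Otu1p,YOD1,1,1
Otu2,Q9UUK3,OTU,OTU,C,,Otu2p,OTUD6B,0,0
Sst2,Q9P371,JAMM,JAMM,CS(endosomes),,NA,STAMBP,0,0
Rpn11,P41878,JAMM,JAMM,NE,26S proteasome,Rpn11p,PSMD14,1,1
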