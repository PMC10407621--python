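id,name,abbrev,smiles,rejection_ann,rejection_exp,censored,split
1,"1,1,1,2-Tetrachloroethane","1,1,1,2-TCA",ClCC(Cl)(Cl)Cl,94.1,99,0,training
2,"1,1,1-Trichloroethane","1,1,1-TCA",CC(Cl)(Cl)Cl,93.1,98,0,training
3,"1,1,2,2-Tetrachloroethane","1,1,2,2-TCA",ClC(Cl)C(Cl)Cl,96.6,97,0,validation
4,"1,1,2-Trichloroethane","1,1,2-TCA",ClCC(Cl)Cl,81.1,86,0,training
5,"1,1-Dichloroethane","1,1-DCA",CC(Cl)Cl,83.7,80,0,training
6,"1,1-Dichloroethene","1,1-DCE",C=C(Cl)Cl,19.2,17,0,training
7,"1,1-Dichloropropene","1,1-DCP",CC=C(Cl)Cl,51.9,45,0,training
8,"1,2,3-Trichlorobenzene","1,2,3-TCB",Clc1cccc(Cl)c1Cl,87.2,91,0,validation
9,"1,2,3-Trichloropropane","1,2,3-TCP",ClCC(Cl)CCl,96.4,95,0,test
10,"1,2,4-Trichlorobenzene","1,2,4-TCB",Clc1ccc(Cl)c(Cl)c1,88.0,79,0,training
11,"1,2,4-Trimethylbenzene","1,2,4-TMB",Cc1ccc(C)c(C)c1,97.6,97,0,training
12,"1,2-Dibromo-3-chloropropane","1,2-DB-3-CP",BrCC(Br)CCl,87.1,97,0,training
13,"1,2-Dibromoethane",EDB,BrCCBr,39.1,40,0,test
14,"1,2-Dichlorobenzene","1,2-DCB",Clc1ccccc1Cl,78.9,83,0,validation
15,"1,2-Dichloroethane","1,2-DCA",ClCCCl,38.2,34,0,training
16,"1,2-Dichloropropane","1,2-DCP",CC(Cl)CCl,82.6,91,0,training
17,"1,3,5-Trimethylbenzene","1,3,5-TMB",Cc1cc(C)cc(C)c1,89.2,99,0,training
18,"1,3-Dichlorobenzene","1,3-DCB",Clc1cccc(Cl)c1,70.0,71,0,training
19,"1,3-Dichloropropane","1,3-DCP",ClCCCCl,60.2,71,0,training
20,"1,4-Dichlorobenzene","1,4-DCB",Clc1ccc(Cl)cc1,62.5,59,0,training
21,"1,4-Dioxane","1,4-D",C1COCCO1,98.5,98,0,training
22,2-Butanone,2-But,CCC(C)=O,86.1,73,0,training
23,2-Chlorotoluene,2-CT,Cc1ccccc1Cl,86.7,88,0,test
24,2-Hexanone,2-Hex,CCCCC(C)=O,93.8,83,0,training
25,4-Chlorotoluene,4-CT,Cc1ccc(Cl)cc1,71.0,67,0,training
26,4-Isopropyltoluene,4-IPT,CC(C)c1ccc(C)cc1,96.6,98,0,validation
27,4-Methyl-2-pentanone,MIBK,CC(C)CC(C)=O,95.9,98,0,training
28,Acetone,Acetone,CC(C)=O,65.2,55,0,test
29,Acetonitrile,Ace-N,CC#N,19.1,23,0,validation
30,Acrylonitrile,Acr-N,C=CC#N,7.5,18,0,test
31,Benzene,Benzene,c1ccccc1,76.3,79,0,training
32,Bromobenzene,BB,Brc1ccccc1,67.1,59,0,training
33,Bromochloromethane,BCM,ClCBr,20.2,25,0,training
34,Bromodichloromethane,BDCM,ClC(Cl)Br,80.4,82,0,training
35,Bromoform,BF,BrC(Br)Br,75.0,85,0,test
36,Bromomethane,BM,CBr,9.7,0,0,training
37,Carbon tetrachloride,C-Tet,ClC(Cl)(Cl)Cl,98.8,97,0,training
38,Chlorobenzene,CB,Clc1ccccc1,67.5,63,0,training
39,Chloroethane,CA,CCCl,12.8,15,0,training
40,Chloroform,CF,ClC(Cl)Cl,91.9,73,0,validation
41,Chloromethane,CM,CCl,12.8,4,0,validation
42,"cis-1,2-Dichloroethene","cis-1,2-DCE",Cl/C=C\Cl,13.4,11,0,test
43,"cis-1,3-Dichloropropene","cis-1,3-DCP",ClC/C=C\Cl,35.8,48,0,training
44,Dibromochloromethane,DBCM,BrC(Br)Cl,74.2,78,0,training
45,Dibromomethane,DBM,BrCBr,10.9,25,0,training
46,Ethylbenzene,EB,CCc1ccccc1,92.1,87,0,training
47,"Hexachloro-1,3-butadiene",HCBD,ClC(Cl)=C(Cl)C(Cl)=C(Cl)Cl,95.7,96,1,validation
48,Isopropyl alcohol,IPA,CC(C)O,83.6,91,0,training
49,Isopropyl benzene,Cumene,CC(C)c1ccccc1,94.7,97,0,training
50,Isopropyl ether,IPE,CC(C)OC(C)C,97.3,99,0,test
51,Methyl tert-butyl ether,MTBE,COC(C)(C)C,97.6,99,0,training
52,Methylene chloride,MC,ClCCl,14.8,10,0,training
53,m-Xylenes,m-Xylenes,Cc1cccc(C)c1,93.9,88,0,validation
54,p-Xylenes,p-Xylenes,Cc1ccc(C)cc1,91.3,88,0,validation
55,Naphthalene,Naph,c1ccc2ccccc2c1,89.0,91,0,training
56,n-Butylbenzene,n-BB,CCCCc1ccccc1,95.8,90,0,training
57,n-Propylbenzene,n-PB,CCCc1ccccc1,93.2,88,0,training
58,o-Xylene,o-Xylene,Cc1ccccc1C,95.5,96,0,training
59,sec-Butylbenzene,s-BB,CCC(C)c1ccccc1,96.4,98,0,test
60,tert-Amyl methyl ether,TAME,CCC(C)(C)OC,98.8,99,0,training
61,tert-Butyl alcohol,TBA,CC(C)(C)O,95.6,99,0,validation
62,tert-Butyl ethyl ether,TBEE,CCOC(C)(C)C,98.6,99,0,test
63,tert-Butylbenzene,TBB,CC(C)(C)c1ccccc1,98.0,96,1,training
64,Tetrachloroethene,PCE,ClC(Cl)=C(Cl)Cl,82.0,83,0,training
65,Toluene,Toluene,Cc1ccccc1,86.0,82,0,training
66,"trans-1,2-Dichloroethene","t-1,2-DCE",Cl/C=C/Cl,13.4,15,0,training
67,"trans-1,3-Dichloropropene","t-1,3-DCP",ClC/C=C/Cl,39.2,27,0,training
68,"trans-1,4-Dichloro-2-butene","t-1,4-DCB",ClC/C=C/CCl,52.3,51,0,training
69,Trichloroethene,TCE,ClC=C(Cl)Cl,42.8,46,0,training
70,Vinyl acetate,VA,CC(=O)OC=C,49.3,46,0,training
71,Vinyl chloride,VC,C=CCl,19.4,17,0,training
72,Vinylbenzene,Styrene,C=Cc1ccccc1,86.6,75,0,test
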