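name,smiles,kfw,chi1,phi,indicator,ws
Benzyl alcohol,OCc1ccccc1,0.447,2.580,-0.323,1,42900
4-Fluorophenol,Oc1ccc(F)cc1,0.525,2.234,-1.110,1,12500
Phenol,Oc1ccccc1,0.661,2.134,-0.540,1,82800
m-Cresol,Cc1cccc(O)c1,0.933,2.545,-0.323,1,22700
Phenethyl alcohol,OCCc1ccccc1,1.318,3.081,0.014,1,20000
3-Methylbenzyl alcohol,Cc1cccc(CO)c1,1.479,2.991,0.014,1,50000
3-Chlorophenol,Oc1cccc(Cl)c1,2.042,2.647,-0.727,1,26000
"3,5-Dimethylphenol",Cc1cc(C)cc(O)c1,2.630,2.956,0.014,1,4880
3-Bromophenol,Oc1cccc(Br)c1,2.884,3.026,-0.762,1,24000
4-Ethylphenol,CCc1ccc(O)cc1,3.981,3.106,0.014,1,4900
4-Chloroaniline,Nc1ccc(Cl)cc1,6.918,2.676,-0.022,1,3900
Phenyl acetate,CC(=O)Oc1ccccc1,7.244,3.023,-1.430,1,4640
Benzonitrile,N#Cc1ccccc1,10.96,2.384,0.753,1,2000
Acetophenone,CC(=O)c1ccccc1,10.96,2.865,-0.605,1,6130
4-Chloroacetophenone,CC(=O)c1ccc(Cl)cc1,43.7,3.342,-0.672,1,111
Methyl benzoate,COC(=O)c1ccccc1,44.7,2.977,-1.430,1,2100
Ethylbenzoate,CCOC(=O)c1ccccc1,131.8,3.565,-1.093,1,720
4-Chloroanisole,COc1ccc(Cl)cc1,234.4,3.036,-0.390,1,237
Chlorobenzene,Clc1ccccc1,251.2,2.477,0.098,1,498
Bromobenzene,Brc1ccccc1,323.6,2.891,0.063,1,410
Iodobenzene,Ic1ccccc1,537.1,3.161,0.692,1,340
Naphthalene,c1ccc2ccccc2c1,676.1,3.405,-0.344,1,31
4-Chlorotoluene,Cc1ccc(Cl)cc1,741.3,3.095,0.435,1,106
Propylbenzene,CCCc1ccccc1,1380,3.471,1.176,1,52.2
1-Methylnaphthalene,Cc1cccc2ccccc12,1819,3.821,-0.007,1,25.8
Biphenyl,c1ccc(c2ccccc2)cc1,2344,4.071,-0.007,1,6.9
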