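name,smiles,kfw,chi1,phi,indicator,mw,ws,log_kow
Benzene,c1ccccc1,58,2,0.165,1,78,1790,2.13
Toluene,Cc1ccccc1,189,2.411,0.502,1,92,526,2.73
o-Xylene,Cc1ccccc1C,485,2.827,0.839,1,106,178,3.12
m-Xylene,Cc1cccc(C)c1,533,2.821,0.839,1,106,161,3.2
p-Xylene,Cc1ccc(C)cc1,564,2.821,0.839,1,106,162,3.15
Ethylbenzene,CCc1ccccc1,566,2.971,0.839,1,106,169,3.15
Cyclopentane,C1CCCC1,712,2.5,0.733,0,70,156,3.01
Methylcyclopentane,CC1CCCC1,1356,2.894,1.07,0,84,42,3.37
Isopropylbenzene,CC(C)c1ccccc1,1412,3.354,1.176,1,120,61.3,3.66
"1,3,5-Trimethylbenzene",Cc1cc(C)cc(C)c1,1451,3.232,1.176,1,120,48.2,3.42
1-Methyl-4-Ethylbenzene,CCc1ccc(C)cc1,1581,3.382,1.176,1,120,94.9,3.63
Cyclohexane,C1CCCCC1,1592,3,1.07,0,84,55,3.44
n-Propylbenzene,CCCc1ccccc1,1664,3.471,1.176,1,120,52.2,3.69
"1,2,4-Trimethylbenzene",Cc1ccc(C)c(C)c1,2183,3.238,1.76,1,120,57,3.63
tert-Butylbenzene,CC(C)(C)c1ccccc1,2185,3.661,1.513,1,134,29.5,4.11
"2,3-Dimethylbutane",CC(C)C(C)C,2359,2.643,1.782,0,86,22.5,3.42
2-Methylpentane,CC(C)CCC,3224,2.77,1.782,0,86,14,3.21
3-Methylpentane,CCC(C)CC,3270,2.808,1.782,0,86,17.9,3.6
1-Methyl-3-Isopropylbenzene,CC(C)c1cccc(C)c1,3284,3.765,1.513,1,134,42.5,4.5
"trans-1,2-Dimethylcyclopentane",CC1CCCC1C,3372,3.207,1.407,0,98,33.9,3.52
1-Methyl-3-n-Propylbenzene,CCCc1cccc(C)c1,3772,3.882,1.513,1,134,9.09,4.67
n-Butylbenzene,CCCCc1ccccc1,3872,3.971,1.513,1,134,11.8,4.38
"1,2-Dimethyl-4-Ethylbenzene",CCc1ccc(C)c(C)c1,3984,3.8,1.513,1,134,12.7,4.5
sec-Butylbenzene,CCC(C)c1ccccc1,4011,3.892,1.513,1,134,17.6,4.57
Isobutylbenzene,CC(C)Cc1ccccc1,4197,3.827,1.513,1,134,10.1,4.68
"cis-1,3-Dimethylcyclopentane",CC1CCC(C)C1,4289,3.288,1.407,0,98,33.9,3.52
"1,3-Dimethyl-2-Ethylbenzene",CCc1c(C)cccc1C,4345,3.805,1.513,1,134,19.6,4.28
Methylcyclohexane,CC1CCCCC1,4657,3.394,1.407,0,98,14,3.61
"cis-trans-cis-1,2,4-Trimethylcyclopentane",CC1C(C)CC(C)C1,5621,3.698,1.744,0,112,14.8,3.94
"trans-1,2-Dimethylcyclohexane",CC1CCCCC1C,6638,3.805,1.744,0,112,5.2,4.01
1-Ethyl-1-methylcyclopentane,CCC1(C)CCCC1,6831,3.768,1.744,0,122,11.6,4.05
"2,2-Dimethylpentane",CC(C)(C)CCC,7349,3.061,2.119,0,100,4.4,3.67
"cis-1,2-Dimethylcyclohexane",CC1CCCCC1C,7826,3.805,1.744,0,112,6,4.01
n-Pentylbenzene,CCCCCc1ccccc1,8195,4.471,1.85,1,148,3.37,4.9
"2,4-Dimethylpentane",CC(C)CC(C)C,8989,3.126,2.119,0,100,5.5,3.63
2-Methylbutylbenzene,CCC(C)Cc1ccccc1,9099,4.365,1.85,1,148,12.7,4.43
"2,2,3-Trimethylbutane",CC(C)C(C)(C)C,9802,3.944,2.119,0,100,28.9,3.59
2-Methylhexane,CC(C)CCCC,10202,3.27,2.119,0,100,2.54,3.71
"3,3-Dimethylpentane",CCC(C)(C)CC,10963,3.121,2.119,0,100,5.92,3.67
3-Methylhexane,CCC(C)CCC,11146,2.9,2.119,0,100,4.95,3.71
"2,3-Dimethylpentane",CC(C)C(C)CC,13074,3.181,2.119,0,100,5.25,3.63
"1,2,4-Triethylbenzene",CCc1ccc(CC)c(CC)c1,16253,4.92,2.187,1,162,2.9,5.11
"1,3,5-Triethylbenzene",CCc1cc(CC)cc(CC)c1,18517,4.914,2.187,1,162,0.014,5.11
"2,2,3-Trimethylpentane",CCC(C)C(C)(C)C,21205,3.481,2.456,0,114,2.4,4.09
"2,5-Dimethylhexane",CC(C)CCC(C)C,23519,3.626,2.456,0,114,9.2,4.12
"2,2-Dimethylhexane",CC(C)(C)CCCC,24504,3.561,2.456,0,114,0.2,4.16
2-Methylheptane,CC(C)CCCCC,25806,3.77,2.456,0,114,7.97,4.2
4-Methylheptane,CCCC(C)CCC,27274,3.808,2.456,0,114,7.97,4.2
3-Ethylhexane,CCC(CC)CCC,28370,3.846,2.456,0,114,7.97,4.2
3-Methylheptane,CCC(C)CCCC,31856,3.808,2.456,0,114,0.792,4.2
"2,3-Dimethylhexane",CC(C)C(C)CCC,33749,3.681,2.456,0,114,9.2,4.12
"2,4-Dimethylhexane",CC(C)CC(C)CC,41133,3.664,2.456,0,114,9.87,4.12
2-Methyloctane,CC(C)CCCCCC,45267,4.27,2.793,0,128,2.87,4.69
"3,3-Diethylpentane",CCC(CC)(CC)CC,63718,4.243,2.793,0,128,2.9,4.65
3-Methyloctane,CCC(C)CCCCC,66682,4.308,2.793,0,128,2.87,4.69
"2,3-Dimethylheptane",CC(C)C(C)CCCC,68675,4.181,2.793,0,128,3.37,4.61
"3,3-Dimethylheptane",CCC(C)(C)CCCC,76013,4.121,2.793,0,128,2.9,4.65
"3,5-Dimethylheptane",CCC(C)CC(C)CC,78829,4.202,2.793,0,128,3.11,4.61
"3,3-Dimethyloctane",CCC(C)(C)CCCCC,82430,4.621,3.13,0,142,2.9,5.14
"2,5-Dimethylheptane",CC(C)CCC(C)CC,84142,4.164,2.793,0,128,3.11,4.61
"3,4-Dimethylheptane",CCC(C)C(C)CCC,93292,4.219,2.793,0,128,3.11,4.61
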