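peak,rt_min,name,formula,compound_class,aglycone,calc_mz_printed,found_mz,error_ppm_printed,rdb_printed,fragments
1,0.304,pentosylhexoside,C11H20O10,saccharide,,311.0984,311.0992,2.7,2,311.1004;179.0560;161.0453;87.0086
2,0.310,theanine,C7H14N2O3,amino acid,,173.0932,173.0932,0.2,2,155.0836;93.0350;84.0459;82.0313
3,0.316,quinic acid,C7H12O6,phenolic acid/quinate ester,,191.0561,191.0564,1.5,2,191.0564;173.0451;171.0292;127.0399;111.0451;93.0347;87.0087;85.0298;83.0500;81.0344
4,0.319,trihexoside,C18H32O16,saccharide,,503.1618,503.1637,3.7,3,503.1654;341.1097;323.0983;281.0891;251.0789;221.0667;179.0558;161.0451;119.0349;113.0246;89.0242
5,0.324,dihexoside,C12H22O11,saccharide,,341.1089,341.1102,3.7,2,341.1095;179.0556;161.0452;149.0446;143.0345;131.0352;119.0348;113.0244;101.0245;95.0140;89.0247
6,0.873,gallic acid,C7H6O5,phenolic acid/quinate ester,,169.0142,169.0148,3.3,5,125.0242
7,1.049,theogallin,C14H16O10,phenolic acid/quinate ester,,343.0671,343.0671,0.1,7,191.0561;127.0397;85.0290
8,1.400,gallocatechin,C15H14O7,flavan-3-ol,,305.0667,305.0671,1.4,9,305.0678;221.0463;219.0672;177.0561;167.0356;139.0407;137.0251;125.0253;109.0300
9,1.771,prodelphinidin B,C30H26O14,proanthocyanidin dimer,,609.1250,609.1265,2.5,18,609.1294;483.0950;441.0835;423.0733;355.0804;305.0665;255.0305;221.0454;179.0340;177.0180;125.0236
10,2.094,epigallocatechin,C15H14O7,flavan-3-ol,,305.0667,305.0671,1.4,9,305.0671;219.0667;167.0353;139.0403;137.0248;125.0248;109.0299
11,2.320,catechin,C15H14O6,flavan-3-ol,,289.0718,289.0722,1.5,9,289.0727;245.0825;221.0821;205.0514;203.0719;187.0402;179.0353;151.0407;137.0251;125.0248;123.0457;109.0300
12,2.515,5-O-caffeoyl quinic acid,C16H18O9,phenolic acid/quinate ester,,353.0877,353.0878,-0.3,8,191.0558;179.0345;173.0459;135.0448;85.0291
13,2.734,coumaroyl quinic acid,C16H18O8,phenolic acid/quinate ester,,337.0931,337.0929,0.6,8,191.0561;173.0452;163.0401;119.0497;93.0344
14,2.904,epicatechin,C15H14O6,flavan-3-ol,,289.0718,289.0722,1.5,9,289.0733;245.0830;221.0831;205.0515;203.0723;187.0409;179.0358;151.0405;137.0250;125.0247;123.0456;109.0299
15,3.074,(epi)gallocatechin gallate 1,C22H18O11,galloylated flavan-3-ol,,457.0776,457.0786,2.1,14,331.0463;305.0673;219.0668;193.0148;169.0146;161.0245;137.0245;125.0246
16,3.191,apigenin 6-C-hexosyl-8-C-hexoside,C27H30O15,flavone C-glycoside,apigenin,593.1512,593.1520,1.4,13,593.1555;575.1398;545.1276;503.1207;473.1109;395.0780;383.0779;353.0672;325.0715;297.0771;221.0452;191.0357
17,3.357,(epi)gallocatechin gallate 2,C22H18O11,galloylated flavan-3-ol,,457.0776,457.0788,2.5,14,331.0476;305.0678;219.0668;193.0148;169.0151;161.0249;137.0246;125.0250
18,3.377,myricetin galloyl hexoside,C28H24O17,acylated flavonol glycoside,myricetin,631.0941,631.0950,1.5,17,631.0979;479.0853;317.0294;316.0225;287.0192;271.0239;178.9978;169.0135
19,3.480,apigenin 6-C-hexosyl-8-C-pentoside,C26H28O14,flavone C-glycoside,apigenin,563.1406,563.1418,2.2,13,563.1442;545.1324;503.1225;473.1113;443.1004;413.0889;383.0782;353.0672;325.0722;297.0771;296.0685
20,3.497,myricetin deoxyhexosyl hexoside,C27H30O17,flavonol O-glycoside,myricetin,625.1410,625.1422,1.9,13,625.1468;463.0914;317.0314;316.0237;300.0286;271.0263;214.0264;178.9990;151.0039
21,3.503,myricetin hexoside,C21H20O13,flavonol O-glycoside,myricetin,479.0831,479.0847,3.3,12,479.0867;317.0309;316.0238;287.0201;271.0256;214.0274;178.9993
22,3.567,myricetin dihexoside,C27H30O18,flavonol O-glycoside,myricetin,641.1373,641.1359,2.1,13,641.1404;479.0857;317.0308;316.0226;271.0239;178.9983;151.0023
23,3.606,epigallocatechin methylgallate,C23H20O11,galloylated flavan-3-ol,,471.0943,471.0933,2.2,14,305.0678;219.0667;183.0308;179.0355;168.0070;161.0251;125.0249
24,3.633,quercetin trihexoside,C33H40O21,flavonol O-glycoside,quercetin,771.1989,771.2004,1.9,14,771.2031;609.1496;343.0461;301.0356;300.0278;271.0247;255.0298;178.9990;151.0036
25,3.681,quercetin galloyl hexoside,C28H24O16,acylated flavonol glycoside,quercetin,615.0992,615.0998,1.0,17,615.1061;463.0920;313.0598;301.0369;300.0287;271.0258;255.0315;179.0003
26,3.691,epicatechin gallate,C22H18O10,galloylated flavan-3-ol,,441.0827,441.0836,2.0,14,441.0841;331.0461;303.0508;289.0715;245.0811;203.0707;193.0137;169.0138;151.0393;137.0236;125.0241;124.0162;109.0291
27,3.703,rutin,C27H30O16,flavonol O-glycoside,quercetin,609.1461,609.1469,1.3,13,609.1504;343.0473;301.0364;300.0286;271.0256;255.0304;178.9988;169.0146;151.0043
28,3.819,isoquercetrin,C21H20O12,flavonol O-glycoside,quercetin,463.0888,463.0887,-0.2,12,463.0919;301.0367;300.0290;299.0200;271.0262;255.0309;243.0310;178.9987;151.0038;121.0291
29,3.825,kaempferol dihexosyl deoxyhexoside,C33H40O20,flavonol O-glycoside,kaempferol,755.2040,755.2046,0.8,14,755.2111;285.0411;284.0327;255.0304;229.0507;151.0023
30,3.842,quercetin hexoside,C21H20O12,flavonol O-glycoside,quercetin,463.0882,463.0887,1.1,12,463.0928;301.0373;300.0293;271.0262;255.0310;243.0305;151.0040
31,3.939,kaempferol hexoside,C21H20O11,flavonol O-glycoside,kaempferol,447.0933,447.0941,2.0,12,285.0405;284.0331;255.0305;227.0351;211.0395;183.0449
32,3.959,kaempferol hexosyl deoxyhexoside,C27H30O15,flavonol O-glycoside,kaempferol,593.1531,593.1512,3.2,13,593.1553;285.0407;284.0329;255.0301;227.0349
33,4.007,methylkaempferol deoxyhexoside,C21H20O11,flavonol O-glycoside,kaempferol,447.0933,447.0942,2.0,12,300.0291;285.0409;284.0333;255.0303;227.0353
34,4.008,epicatechin methylgallate,C23H20O10,galloylated flavan-3-ol,,455.0995,455.0984,2.5,14,289.0724;245.0819;183.0301;168.0070;125.0242
35,4.018,epiafzelechin gallate,C22H18O9,galloylated flavan-3-ol,,425.0881,425.0883,0.7,14,425.0910;287.0574;273.0777;255.0666;243.0690;211.0760;169.0144;125.0246;97.0297
36,4.386,camelliquercitoside B,C42H46O23,acylated flavonol glycoside,quercetin,917.2357,917.2361,0.4,20,917.2433;771.2075;753.1915;301.0355;300.0277;299.0198;271.0246;178.9977
37,4.419,camelliquercitoside A,C47H54O27,acylated flavonol glycoside,quercetin,1049.2780,1049.2789,0.9,21,1049.2868;903.2491;885.2401;301.0361;300.0285;299.0200
38,4.420,quercetin coumaroyl hexoside,C30H26O14,acylated flavonol glycoside,quercetin,609.1250,609.1258,1.3,18,609.1308;463.0900;301.0358;300.0278;271.0240;255.0319;227.0371;179.0004;151.0030
39,4.447,camelliquercitoside C,C41H44O22,acylated flavonol glycoside,quercetin,887.2251,887.2263,1.3,20,887.2336;741.1947;723.1846;573.1334;301.0361;300.0282;299.0196;271.0260;255.0289;178.9988;151.0039
40,4.550,camelliquercitoside D,C36H36O18,acylated flavonol glycoside,quercetin,755.1829,755.1838,1.2,19,755.1883;609.1495;591.1391;301.0359;300.0276;299.0193;271.0242;255.0292;178.9979;151.0033
41,4.553,camellikaempferoside C,C42H46O22,acylated flavonol glycoside,kaempferol,901.2408,901.2419,1.2,20,901.2487;755.2105;737.2002;615.1976;285.0412;284.0333;283.0251;229.0525;187.0387;145.0297
42,4.654,kaempferol coumaroylhexoside,C30H26O13,acylated flavonol glycoside,kaempferol,593.1301,593.1325,4.1,18,593.1322;447.0948;285.0394;284.0322;255.0289;227.0334;145.0279
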