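acronym,name,group,mode,organ,unit,mean,sd_printed,range_printed,cov_pct,p_geno,p_p,p_gxp,h2
CRA,Angle of crown roots,Angle,manual,root,deg,57.0,90.0,17.8,31.3,0.968,<0.001,0.006,-
AvD,Average diameter,Diameter,image,root,mm,8.4,7.2,0.6,7.7,0.084,0.023,0.025,-
AHS,Average hole size,Area,image,root,mm^2,127.2,543.1,49.7,39.1,<0.001,0.002,0.338,0.28
ARO,Average root orientation,Angle,image,root,deg,48.6,18.3,2.4,4.9,<0.001,0.003,0.481,-
BRL,Brace root length,Length,manual,root,cm,17.2,30.0,4.0,23.5,<0.001,0.189,<0.001,-
BA1a,First arm brace root angle first whorl,Angle,manual,root,deg,107.2,180.0,37.5,34.9,0.605,0.004,0.005,-
BA1b,First arm brace root angle second whorl,Angle,manual,root,deg,107.8,182.0,42.6,39.5,0.04,<0.001,0.01,0.02
BA2a,Second arm brace root angle first whorl,Angle,manual,root,deg,113.8,180.0,38.5,33.8,<0.001,0.352,0.116,0.54
BA2b,Second arm brace root angle second whorl,Angle,manual,root,deg,105.4,175.0,44.0,41.7,0.241,0.26,0.016,-
BDBr,Branching of brace roots,Number,manual,root,root no./cm,5.2,21.0,3.5,67.2,0.038,<0.001,0.009,0.04
BDCr,Branching of crown roots,Number,manual,root,root no./cm,5.7,14.0,2.8,50.1,0.333,0.017,0.155,-
CoA,Convex area,Area,image,root,mm^2,"389,247","1,140,215","176,864",45.4,<0.001,0.006,0.357,1.00
CRL,Crown root length,Length,manual,root,cm,17.5,29.3,3.7,21.4,<0.001,0.003,0.002,-
Dep,Depth,Length,image,root,mm,821.0,702.2,128.8,15.7,<0.001,0.286,0.639,-
Hol,Holes,Number,image,root,,427.8,"1,566.0",223.1,52.2,<0.001,<0.001,0.003,0.58
LRA,Lower root area,Area,image,root,mm^2,"115,848","381,202.0","57,533",49.7,<0.001,0.462,0.102,0.98
MxD,Maximum diameter,Diameter,image,root,mm,35.7,37.0,5.8,16.3,0.024,0.156,0.265,-
MxNR,Maximum number of roots,Number,image,root,,30.3,53.0,7.9,26.0,<0.001,0.014,0.028,-
MW,Maximum width,Width,image,root,mm,708.5,"1,111.0",222.1,31.3,<0.001,0.008,0.232,0.42
MeD,Median diameter,Diameter,image,root,mm,7.5,9.6,0.7,9.4,<0.001,0.151,0.007,-
MNR,Median number of roots,Number,image,root,,10.0,26.0,4.3,43.0,<0.001,0.007,0.015,0.54
MAF,Medium angle frequency,Number,image,root,,0.3,0.2,0.0,8.1,<0.001,0.465,0.795,-
NeA,Network area,Area,image,root,mm^2,"134,593","397,535.0","65,490",48.7,<0.001,0.012,0.002,0.22
NCR,Number of crown roots,Number,manual,root,,4.2,9.0,1.8,41.4,0.935,<0.001,<0.001,-
NRT,Number of root tips,Number,image,root,,514.3,"1,412.0",276.4,53.7,<0.001,<0.001,0.018,0.62
NBR,Number of brace roots,Number,manual,root,,34.0,84.0,13.1,38.3,<0.001,<0.001,<0.001,0.18
NoW,Numbers of aboveground whorls,Number,manual,root,,3.3,8.0,1.2,35.4,<0.001,0.001,0.03,0.04
Per,Perimeter,Length,image,root,mm,"29,021","72,219.0","13,029",44.9,<0.001,0.004,0.02,0.07
PAD1,Projected area diameter-range 1,Area,image,root,mm^2,977.5,"2,693.0",509.2,52.1,<0.001,<0.001,0.084,0.40
PAD2,Projected area diameter-range 2,Area,image,root,mm^2,"20,349","48,596.0","8,578.0",42.2,<0.001,<0.001,0.155,0.44
PAD3,Projected area diameter-range 3,Area,image,root,mm^2,"181,655","619,355.0","94,510",52.0,<0.001,0.01,0.001,0.55
RDW,Root dry weight,Biomass,manual,root,g,78.2,437.5,88.9,113.7,0.104,0.005,0.589,-
RFW,Root fresh weight,Biomass,manual,root,g,189.0,"1,235.0",244.9,129.6,<0.001,0.003,0.193,0.89
RLD1,Root length diameter-range 1,Length,image,root,mm,720.8,"2,007.0",378.3,52.5,<0.001,<0.001,0.08,0.37
RLD2,Root length diameter-range 2,Length,image,root,mm,"5,373.0","12,899.0","2,287.0",42.6,<0.001,<0.001,0.173,0.43
RLD3,Root length diameter-range 3,Length,image,root,mm,"17,965","56,438.0","9,004.0",50.1,<0.001,0.007,0.002,0.98
ShAF,Shallow angle frequency,Number,image,root,,0.3,0.3,0.0,10.2,<0.001,0.002,0.126,-
SDW,Shoot dry weight,Biomass,manual,shoot,g,196.0,905.8,153.7,78.4,0.221,<0.001,<0.001,-
SFW,Shoot fresh weight,Biomass,manual,shoot,g,333.7,"1,174.0",260.9,78.2,0.929,0.29,0.021,-
Sol,Solidity,Area,image,root,,0.3,0.4,0.1,20.2,0.426,<0.001,0.074,-
StAF,Steep angle frequency,Number,image,root,,0.4,0.3,0.0,10.9,<0.001,0.009,0.784,-
SAD1,Surface area diameter-range 1,Diameter,image,root,mm,"3,071.0","8,459.0","1,600.0",52.1,<0.001,<0.001,0.084,0.40
SAD2,Surface area diameter-range 2,Diameter,image,root,mm,"63,929","152,670.0","26,947",42.2,<0.001,<0.001,0.155,0.44
SAD3,Surface area diameter-range 3,Diameter,image,root,mm,"570,708","1,945,819","296,924",52.0,<0.001,0.01,0.001,0.23
SuA,Surface area,Area,image,root,mm^2,"637,708","2,067,990","321,385",50.4,<0.001,0.007,0.001,0.77
TRL,Total root length,Length,image,root,mm,"24,059","67,412.0","11,438",47.5,<0.001,0.003,0.006,0.47
VDR1,Volume diameter-range 1,Volume,image,root,mm^3,"1,140.0","3,154.0",590.0,51.8,<0.001,<0.001,0.09,0.40
VDR2,Volume diameter-range 2,Volume,image,root,mm^3,"63,377","150,717.0","26,524",41.9,<0.001,<0.001,0.14,0.41
VDR3,Volume diameter-range 3,Volume,image,root,mm^3,"1,717,684","6,161,094","911,057",53.0,<0.001,0.01,0.001,0.62
Vol,Volume,Volume,image,root,mm^3,"1,782,201","6,280,013","932,323",52.3,<0.001,0.009,0.001,0.62
WDR,Width-to-depth ratio,Width,image,root,,0.9,1.6,0.2,25.4,<0.001,0.169,0.029,-
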