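site_group,stage,index_n,non_index_n,non_cancer_n
"All Types",I,66737,31785,170318
"All Types",II,85179,39125,201719
"All Types",III,93826,9468,49183
"All Types",IV,171607,4279,26698
"All Types",Unknown,119567,11375,73651
"Bladder",I,3060,1251,6129
"Bladder",II,2567,428,1850
"Bladder",III,1224,116,725
"Bladder",IV,2867,126,518
"Bladder",Unknown,903,115,837
"Breast, All",I,11259,10032,54126
"Breast, All",II,15448,5289,28748
"Breast, All",III,9788,1281,6227
"Breast, All",IV,7377,94,1011
"Breast, All",Unknown,3733,509,3597
"Breast, HR-Positive",I,8929,8618,45559
"Breast, HR-Positive",II,11783,4049,21802
"Breast, HR-Positive",III,6935,911,4468
"Breast, HR-Positive",IV,4728,64,706
"Breast, HR-Positive",Unknown,1635,248,2030
"Breast, HR-Negative",I,1906,1156,6422
"Breast, HR-Negative",II,2944,1153,5722
"Breast, HR-Negative",III,2284,340,1626
"Breast, HR-Negative",IV,1562,21,215
"Breast, HR-Negative",Unknown,399,123,479
"Breast, HR-Unknown",I,420,268,2008
"Breast, HR-Unknown",II,613,126,1206
"Breast, HR-Unknown",III,435,49,201
"Breast, HR-Unknown",IV,1051,11,95
"Breast, HR-Unknown",Unknown,1646,166,1102
"Cervix",I,586,284,1358
"Cervix",II,507,133,420
"Cervix",III,883,120,429
"Cervix",IV,984,10,173
"Cervix",Unknown,388,51,171
"Colon/Rectum",I,4806,2896,17869
"Colon/Rectum",II,7853,2332,15364
"Colon/Rectum",III,12134,1952,11928
"Colon/Rectum",IV,18555,206,1755
"Colon/Rectum",Unknown,4078,950,4330
"Esophagus",I,999,78,784
"Esophagus",II,1429,82,500
"Esophagus",III,1789,84,328
"Esophagus",IV,3841,22,240
"Esophagus",Unknown,1452,33,286
"Kidney",I,4428,2518,12622
"Kidney",II,1363,279,1595
"Kidney",III,2881,352,2078
"Kidney",IV,5901,79,608
"Kidney",Unknown,1140,214,944
"Larynx",I,1065,337,1872
"Larynx",II,659,156,640
"Larynx",III,812,131,505
"Larynx",IV,1718,153,673
"Larynx",Unknown,362,51,319
"Liver/Intrahepatic Bile Duct",I,4353,345,1559
"Liver/Intrahepatic Bile Duct",II,2462,172,840
"Liver/Intrahepatic Bile Duct",III,3958,20,373
"Liver/Intrahepatic Bile Duct",IV,3497,16,272
"Liver/Intrahepatic Bile Duct",Unknown,4427,72,577
"Lung, All",I,14134,1115,11476
"Lung, All",II,4626,158,1717
"Lung, All",III,30907,482,5420
"Lung, All",IV,65620,377,4604
"Lung, All",Unknown,12182,238,3145
"Lung, Non-Small-Cell",I,10742,953,9353
"Lung, Non-Small-Cell",II,3363,119,1323
"Lung, Non-Small-Cell",III,18255,329,3123
"Lung, Non-Small-Cell",IV,33160,204,2166
"Lung, Non-Small-Cell",Unknown,4249,54,852
"Lung, Small-Cell",I,615,13,217
"Lung, Small-Cell",II,304,6,71
"Lung, Small-Cell",III,5091,46,759
"Lung, Small-Cell",IV,12285,34,701
"Lung, Small-Cell",Unknown,1191,10,158
"Lymphoma",I,4305,1334,7059
"Lymphoma",II,2963,602,3768
"Lymphoma",III,4020,613,3574
"Lymphoma",IV,8958,1091,6672
"Lymphoma",Unknown,1732,358,1924
"Melanoma",I,3101,5151,21193
"Melanoma",II,1706,489,2856
"Melanoma",III,1544,244,843
"Melanoma",IV,1442,33,257
"Melanoma",Unknown,1126,450,2776
"Oral Cavity/Pharynx",I,1086,671,2508
"Oral Cavity/Pharynx",II,1128,249,1460
"Oral Cavity/Pharynx",III,1826,339,1588
"Oral Cavity/Pharynx",IV,6736,803,3801
"Oral Cavity/Pharynx",Unknown,2201,481,2100
"Ovary",I,799,368,1626
"Ovary",II,826,61,307
"Ovary",III,5170,105,617
"Ovary",IV,4333,47,357
"Ovary",Unknown,1457,64,365
"Pancreas",I,1389,57,383
"Pancreas",II,6175,55,712
"Pancreas",III,2415,7,109
"Pancreas",IV,14634,42,605
"Pancreas",Unknown,3858,55,444
"Prostate",I,19,19,164
"Prostate",II,29688,27419,134472
"Prostate",III,5637,2521,8560
"Prostate",IV,9236,627,3169
"Prostate",Unknown,4540,1766,9328
"Stomach",I,1807,256,1896
"Stomach",II,1312,77,491
"Stomach",III,1456,66,326
"Stomach",IV,6241,62,424
"Stomach",Unknown,2074,253,1395
"Thyroid",I,363,1857,7488
"Thyroid",II,192,684,1516
"Thyroid",III,593,394,2668
"Thyroid",IV,1503,304,784
"Thyroid",Unknown,269,370,851
"Uterus",I,3407,3291,17318
"Uterus",II,591,258,1607
"Uterus",III,2394,424,1836
"Uterus",IV,2062,47,306
"Uterus",Unknown,2265,266,1417
"Other Types",I,2872,1095,4614
"Other Types",II,3490,576,2674
"Other Types",III,3710,432,1519
"Other Types",IV,5899,173,638
"Other Types",Unknown,70888,5323,39092
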