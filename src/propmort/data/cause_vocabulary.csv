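cod_code,kind,detail_label
"Bladder",cancer,"Bladder"
"Breast",cancer,"Breast, All"
"Brain/Other Nervous System",cancer,"Brain/Other Nervous System"
"Cervix",cancer,"Cervix"
"Colon/Rectum",cancer,"Colon/Rectum"
"Esophagus",cancer,"Esophagus"
"Kidney",cancer,"Kidney"
"Larynx",cancer,"Larynx"
"Leukemia",cancer,"Leukemia"
"Liver/Intrahepatic Bile Duct",cancer,"Liver/Intrahepatic Bile Duct"
"Lung",cancer,"Lung, All"
"Lymphoma",cancer,"Lymphoma"
"Melanoma",cancer,"Melanoma"
"Myeloma",cancer,"Myeloma"
"Oral Cavity/Pharynx",cancer,"Oral Cavity/Pharynx"
"Ovary",cancer,"Ovary"
"Pancreas",cancer,"Pancreas"
"Prostate",cancer,"Prostate"
"Stomach",cancer,"Stomach"
"Thyroid",cancer,"Thyroid"
"Uterus",cancer,"Uterus"
"Other Cancer",cancer,"Other Types"
"Tuberculosis",noncancer,"Other Infectious Diseases"
"Syphilis",noncancer,"Other Infectious Diseases"
"Other Infectious and Parasitic Diseases",noncancer,"Other Infectious Diseases"
"Septicemia",noncancer,"Septicemia"
"Diabetes Mellitus",noncancer,"Diabetes"
"Alzheimer Disease",noncancer,"Alzheimer Disease"
"Diseases of Heart",noncancer,"Heart Disease"
"Hypertension without Heart Disease",noncancer,"Other Circulatory Diseases"
"Cerebrovascular Diseases",noncancer,"Cerebrovascular Disease"
"Atherosclerosis",noncancer,"Other Circulatory Diseases"
"Aortic Aneurysm and Dissection",noncancer,"Other Circulatory Diseases"
"Other Diseases of Arteries, Arterioles, Capillaries",noncancer,"Other Circulatory Diseases"
"Pneumonia and Influenza",noncancer,"Pneumonia/Influenza"
"Chronic Obstructive Pulmonary Disease and Allied Conditions",noncancer,"COPD"
"Stomach and Duodenal Ulcers",noncancer,"Other"
"Chronic Liver Disease and Cirrhosis",noncancer,"Chronic Liver Disease/Cirrhosis"
"Nephritis, Nephrotic Syndrome and Nephrosis",noncancer,"Nephritis/Nephrosis"
"Complications of Pregnancy, Childbirth, Puerperium",noncancer,"Other"
"Congenital Anomalies",noncancer,"Other"
"Certain Conditions Originating in Perinatal Period",noncancer,"Other"
"Symptoms, Signs and Ill-Defined Conditions",noncancer,"Other"
"Accidents and Adverse Effects",noncancer,"Accidents/External Causes"
"Suicide and Self-Inflicted Injury",noncancer,"Suicide/Self-Injury"
"Homicide and Legal Intervention",noncancer,"Accidents/External Causes"
"Other Cause of Death",noncancer,"Other"
"In Situ, Benign or Unknown Behavior Neoplasm",noncancer,"Other"
"Unknown/Missing Cause",unknown,""
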