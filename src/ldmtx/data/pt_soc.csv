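pt,soc
Thrombocytopenia,Blood and lymphatic system disorders
Pancytopenia,Blood and lymphatic system disorders
Febrile neutropenia,Blood and lymphatic system disorders
Neutropenia,Blood and lymphatic system disorders
Anaemia,Blood and lymphatic system disorders
Transaminases increased,Investigations
Blood creatinine increased,Investigations
Hepatic function abnormal,Hepatobiliary disorders
Hepatotoxicity,Hepatobiliary disorders
Toxic epidermal necrolysis,Skin and subcutaneous tissue disorders
Erythrodermic psoriasis,Skin and subcutaneous tissue disorders
Rash,Skin and subcutaneous tissue disorders
Alopecia,Skin and subcutaneous tissue disorders
Pulmonary toxicity,"Respiratory, thoracic and mediastinal disorders"
Pneumonitis,"Respiratory, thoracic and mediastinal disorders"
Interstitial lung disease,"Respiratory, thoracic and mediastinal disorders"
Rheumatoid lung,"Respiratory, thoracic and mediastinal disorders"
Stomatitis,Gastrointestinal disorders
Nausea,Gastrointestinal disorders
Vomiting,Gastrointestinal disorders
Diarrhoea,Gastrointestinal disorders
Fatigue,General disorders and administration site conditions
Pyrexia,General disorders and administration site conditions
Malaise,General disorders and administration site conditions
Arthralgia,Musculoskeletal and connective tissue disorders
Synovitis,Musculoskeletal and connective tissue disorders
Tenosynovitis,Musculoskeletal and connective tissue disorders
Hand deformity,Musculoskeletal and connective tissue disorders
Headache,Nervous system disorders
Dizziness,Nervous system disorders
Sepsis,Infections and infestations
Pneumonia,Infections and infestations
B-cell lymphoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Euphoric mood,Psychiatric disorders
Dry eye,Eye disorders
Renal failure,Renal and urinary disorders
Acute kidney injury,Renal and urinary disorders
Fall,"Injury, poisoning and procedural complications"
Accidental overdose,"Injury, poisoning and procedural complications"
Post procedural complication,"Injury, poisoning and procedural complications"
Product quality issue,Product issues
Economic problem,Social circumstances
Knee arthroplasty,Surgical and medical procedures
Rheumatoid arthritis,Musculoskeletal and connective tissue disorders
Psoriasis,Skin and subcutaneous tissue disorders
Psoriatic arthropathy,Musculoskeletal and connective tissue disorders
Crohn's disease,Gastrointestinal disorders
Renal impairment,Renal and urinary disorders
Chronic kidney disease,Renal and urinary disorders
Renal disorder,Renal and urinary disorders
Anuria,Renal and urinary disorders
Oliguria,Renal and urinary disorders
Azotaemia,Renal and urinary disorders
Uraemia,Renal and urinary disorders
Cardiorenal syndrome,Renal and urinary disorders
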