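pt,hlt,hlt_code
Renal failure,Renal failure and impairment,10038443
Renal impairment,Renal failure and impairment,10038443
Chronic kidney disease,Renal failure and impairment,10038443
Acute kidney injury,Renal failure and impairment,10038443
Renal disorder,Renal failure and impairment,10038443
Anuria,Renal failure and impairment,10038443
Oliguria,Renal failure and impairment,10038443
Azotaemia,Complications of renal failure,10010180
Uraemia,Complications of renal failure,10010180
Cardiorenal syndrome,Complications of renal failure,10010180
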