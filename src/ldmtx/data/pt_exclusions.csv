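pt,excluded_class
Product quality issue,product issues
Economic problem,social environment
Fall,injuries
Accidental overdose,poisoning
Post procedural complication,surgical complications
Knee arthroplasty,medical procedures
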