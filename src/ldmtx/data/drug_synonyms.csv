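variant,generic
methotrexate,methotrexate
MTX,methotrexate
Trexall,methotrexate
Rheumatrex,methotrexate
Otrexup,methotrexate
methotrexate sodium,methotrexate
metotrexate,methotrexate
METHOTREXATE TAB,methotrexate
prednisone,prednisone
Deltasone,prednisone
ibuprofen,ibuprofen
Advil,ibuprofen
Motrin,ibuprofen
folic acid,folic acid
Folvite,folic acid
etanercept,etanercept
Enbrel,etanercept
adalimumab,adalimumab
Humira,adalimumab
lisinopril,lisinopril
Zestril,lisinopril
Prinivil,lisinopril
furosemide,furosemide
Lasix,furosemide
hydroxychloroquine,hydroxychloroquine
Plaquenil,hydroxychloroquine
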