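region,sector,month,molecule,brand,role,form,strength,dollars,units
CANADA,drugstore,2016-07,insulin glargine,Lantus,originator,all,all,141135286.00,7328068
CANADA,drugstore,2016-07,insulin glargine,Basaglar,biosimilar,all,all,9402061.00,619155
CANADA,drugstore,2016-07,filgrastim,Neupogen,originator,all,all,204152590.00,1033508
CANADA,drugstore,2016-07,filgrastim,Grastofil,biosimilar,all,all,62061576.00,382254
CANADA,drugstore,2016-07,infliximab,Remicade,originator,all,all,2192819808.00,2190467
CANADA,drugstore,2016-07,infliximab,Inflectra,biosimilar,all,all,37202503.00,67330
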