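pesticide_cas,pesticide_name,value,unit
309-00-2,aldrin,0.03,ug/L
60-57-1,dieldrin,0.03,ug/L
94-75-7,"2,4-D",30,ug/L
76-44-8,heptachlor,0.03,ug/L
58-89-9,lindane,2,ug/L
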