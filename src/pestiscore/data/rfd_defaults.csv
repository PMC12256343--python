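pesticide_cas,pesticide_name,rfd_mg_per_kg_day,source
309-00-2,aldrin,0.00003,IRIS
60-57-1,dieldrin,0.00005,IRIS
76-44-8,heptachlor,0.0005,IRIS
58-89-9,lindane,0.0003,IRIS
94-75-7,"2,4-D",0.01,IRIS
1912-24-9,atrazine,0.035,IRIS
2921-88-2,chlorpyrifos,0.003,IRIS
121-75-5,malathion,0.02,IRIS
333-41-5,diazinon,0.0007,IRIS
60-51-5,dimethoate,0.0002,IRIS
1563-66-2,carbofuran,0.005,IRIS
51218-45-2,metolachlor,0.15,IRIS
15972-60-8,alachlor,0.01,IRIS
138261-41-3,imidacloprid,0.057,OPP
141-66-2,dicrotophos,0.0001,OPP
2385-85-5,mirex,0.0002,IRIS
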