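# Default 30-pesticide regulation panel: commonly detected and regulated
# pesticides in freshwater monitoring. One CAS registry number per line.
1912-24-9    # atrazine
122-34-9     # simazine
330-54-1     # diuron
34123-59-6   # isoproturon
2921-88-2    # chlorpyrifos
121-75-5     # malathion
56-38-2      # parathion
333-41-5     # diazinon
60-51-5      # dimethoate
1563-66-2    # carbofuran
63-25-2      # carbaryl
116-06-3     # aldicarb
58-89-9      # lindane
309-00-2     # aldrin
60-57-1      # dieldrin
72-20-8      # endrin
76-44-8      # heptachlor
57-74-9      # chlordane
50-29-3      # p,p'-DDT
115-29-7     # endosulfan
118-74-1     # hexachlorobenzene
72-43-5      # methoxychlor
94-75-7      # 2,4-D
94-74-6      # MCPA
1071-83-6    # glyphosate
34256-82-1   # acetochlor
15972-60-8   # alachlor
51218-45-2   # metolachlor
1582-09-8    # trifluralin
138261-41-3  # imidacloprid
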