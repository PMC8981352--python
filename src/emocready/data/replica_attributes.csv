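facility_id,country,ownership,csec_capable
F01,Kenya,private,1
F02,Kenya,private,1
F03,Kenya,private,1
F04,Kenya,private,1
F05,Uganda,government,1
F06,Uganda,government,1
F07,Uganda,government,1
F08,Uganda,government,1
F09,Uganda,government,1
F10,Uganda,government,1
F11,Kenya,government,0
F12,Kenya,government,0
F13,Kenya,government,0
F14,Kenya,government,0
F15,Kenya,government,0
F16,Kenya,government,0
F17,Kenya,government,0
F18,Kenya,government,0
F19,Kenya,government,0
F20,Kenya,government,0
F21,Kenya,government,0
F22,Kenya,government,0
F23,Kenya,government,0
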