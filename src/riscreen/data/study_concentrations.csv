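sample_id,Procymidone,Chlorpyrifos,Fipronil
CX01,94.77,ND,ND
CX02,47.11,ND,ND
CX03,60.75,ND,ND
CX04,42.89,ND,ND
CX05,29.91,ND,ND
CX06,71.73,ND,ND
CX07,49.85,ND,ND
CX08,31.75,ND,ND
CX09,ND,485.92,ND
CX10,28.25,ND,ND
CX11,56.13,ND,ND
CX12,56.95,ND,ND
CX13,2841.54,ND,ND
CX14,ND,ND,ND
CX15,69.50,ND,ND
CX16,159.29,ND,ND
CX17,35.61,ND,ND
CX18,ND,ND,28.62
CX19,3712.16,ND,ND
CX20,77.30,ND,ND
CX21,64.58,ND,ND
CX22,ND,ND,193.12
CX23,ND,ND,ND
CX24,61.62,ND,38.28
CX25,44.16,ND,ND
CX26,77.72,ND,ND
CX27,ND,ND,64.21
CX28,71.27,ND,ND
CX29,ND,ND,ND
CX30,142.19,ND,ND
CX31,66.31,ND,ND
CX32,81.09,ND,ND
CX33,ND,ND,ND
CX34,ND,ND,ND
CX35,57.36,ND,ND
CX36,82.61,ND,ND
CX37,ND,ND,ND
CX38,ND,ND,ND
CX39,85.36,ND,ND
CX40,96.77,ND,ND
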