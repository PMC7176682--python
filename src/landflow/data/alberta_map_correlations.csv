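map,scalehigh.waterhigh.HF,scalehigh.waterhigh.HU,scalehigh.waterlow.HF,scalehigh.waterlow.HU,scalelow.waterhigh.HF,scalelow.waterhigh.HU,scalelow.waterlow.HF,scalelow.waterlow.HU
scalehigh.waterhigh.HF,1.00,0.79,0.73,0.58,0.83,0.85,0.64,0.67
scalehigh.waterhigh.HU,0.79,1.00,0.41,0.54,0.56,0.65,0.34,0.43
scalehigh.waterlow.HF,0.73,0.41,1.00,0.78,0.78,0.77,0.91,0.91
scalehigh.waterlow.HU,0.58,0.54,0.78,1.00,0.57,0.64,0.66,0.75
scalelow.waterhigh.HF,0.83,0.56,0.78,0.57,1.00,0.94,0.85,0.82
scalelow.waterhigh.HU,0.85,0.65,0.77,0.64,0.94,1.00,0.78,0.85
scalelow.waterlow.HF,0.64,0.34,0.91,0.66,0.85,0.78,1.00,0.94
scalelow.waterlow.HU,0.67,0.43,0.91,0.75,0.82,0.85,0.94,1.00
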