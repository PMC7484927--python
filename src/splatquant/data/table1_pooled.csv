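role,metric,without_eos,with_eos
operatory,mean_frequency,5,4
operatory,mean_intensity_pct,2.9,0.72
clinician,mean_frequency,4,4
clinician,mean_intensity_pct,0.81,0.54
assistant,mean_frequency,2,2
assistant,mean_intensity_pct,1.01,0.24
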