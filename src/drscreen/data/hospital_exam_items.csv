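item,cost_usd
medical_service,8.48
fundus_photography,4.74
optical_coherence_tomography,13.85
visual_acuity_and_iop,0.78
transportation_and_accommodation,63.76
internal_medical_examination,8.39
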