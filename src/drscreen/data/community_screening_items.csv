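item,kind,units,unit_cost_usd,annual_cost_usd
nonmydriatic_retinal_camera,capital,1,24000,
visual_acuity_chart,capital,1,250,
laptop,capital,1,500,
medical_staff,recurring,6,6500,39000
posters_leaflets_loose_expenses,recurring,,,700
casual_supporting_personnel,recurring,,,640
transportation,recurring,,,3000
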