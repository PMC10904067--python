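item,kind,units,unit_cost_usd,annual_cost_usd
computer_software_peripherals,capital,1,9000,
installation,capital,1,5000,
contract_cost_other_organizations,recurring,1,1700,1700
medical_staff_specialists,recurring,10,2500,25000
medical_staff_technicians,recurring,2,2500,5000
maintenance,recurring,1,2000,2000
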