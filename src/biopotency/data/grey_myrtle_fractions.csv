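id,label,role,solvent,ic50_value,ic50_unit,ic50_sd,weight_value,weight_unit,dry_source_mass_g,parent_id,retention_time_min
dcm,Original DCM extract,extract,DCM,14.09,ug/mL,,4000,mg,,,
f01,F-1,fraction,,68.8,ug/mL,,1.8,mg,,dcm,
f02,F-2,fraction,,57.0,ug/mL,,9.4,mg,,dcm,
f03,F-3,fraction,,62.2,ug/mL,,9.2,mg,,dcm,
f04,F-4,fraction,,44.1,ug/mL,,6.6,mg,,dcm,24.7
f05,F-5,fraction,,35.8,ug/mL,,6.9,mg,,dcm,
f06,F-6,fraction,,36.0,ug/mL,,7,mg,,dcm,
f07,F-7,fraction,,25.6,ug/mL,,3.5,mg,,dcm,
f08,F-8,fraction,,15.9,ug/mL,,4.5,mg,,dcm,39.1
f09,F-9,fraction,,16.2,ug/mL,,4,mg,,dcm,41.7
f10,F-10,fraction,,16.3,ug/mL,,6.6,mg,,dcm,
f11,F-11,fraction,,17.1,ug/mL,,10.8,mg,,dcm,
f12,F-12,fraction,,14.5,ug/mL,,12,mg,,dcm,
f13,F-13,fraction,,8.6,ug/mL,,4.9,mg,,dcm,
f14,F-14,fraction,,10.3,ug/mL,,3.5,mg,,dcm,
f15,F-15,fraction,,8.3,ug/mL,,2.1,mg,,dcm,50.3
f16,F-16,fraction,,11.5,ug/mL,,5.7,mg,,dcm,
f17,F-17,fraction,,6.7,ug/mL,,6,mg,,dcm,
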