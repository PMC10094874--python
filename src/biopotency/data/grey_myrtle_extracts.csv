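id,label,role,solvent,ic50_value,ic50_unit,ic50_sd,weight_value,weight_unit,dry_source_mass_g,parent_id,retention_time_min
leaves,Grey Myrtle leaves,plant,,,,,,,,,
etoh_single,Single ethanolic extract,extract,EtOH,10.02,ug/mL,3.13,3.0,g,75,leaves,
hexane_seq,Sequential hexane extract,extract,Hexane,39.11,ug/mL,6.82,1.5,g,230,leaves,
dcm_seq,Sequential DCM extract,extract,DCM,14.09,ug/mL,0.81,6.0,g,230,leaves,
etoac_seq,Sequential EtOAc extract,extract,EtOAc,18.25,ug/mL,7.60,2.9,g,230,leaves,
etoh_seq,Sequential EtOH extract,extract,EtOH,69.25,ug/mL,13.33,6.9,g,230,leaves,
meoh_seq,Sequential MeOH extract,extract,MeOH,49.93,ug/mL,8.76,3.2,g,230,leaves,
water_seq,Sequential water extract,extract,Water,80.25,ug/mL,17.18,5.6,g,230,leaves,
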