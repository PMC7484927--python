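site_id,role,distance_m,clock_angle_deg,height_class
patient,patient,0.35,180,chair
site_71,operatory,0.22,30,floor
assistant_chair,operatory,0.24,60,chair
bracket_table,operatory,0.60,270,table
site_40,operatory,0.80,90,floor
site_43,operatory,1.33,120,floor
clinician_chest,clinician,0.30,150,person
clinician_visor_front,clinician,0.32,140,person
assistant_chest,assistant,0.35,210,person
assistant_visor_front,assistant,0.32,220,person
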