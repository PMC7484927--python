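site_id,role,distance_m,clock_angle_deg,height_class
patient,patient,0.35,180,chair
site_18,operatory,0.50,90,floor
assistant_chair,operatory,0.24,60,chair
bracket_table,operatory,0.60,270,table
operating_light,operatory,0.75,0,ceiling
site_24,operatory,0.90,150,floor
site_25,operatory,1.10,300,floor
screen,operatory,1.20,330,person
site_28,operatory,1.34,240,floor
clinician_chest,clinician,0.30,150,person
clinician_visor_front,clinician,0.32,140,person
assistant_chest,assistant,0.35,210,person
assistant_visor_front,assistant,0.32,220,person
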