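code,procedure,operatory_type,duration,variation,operatory_frequency_n,operatory_mean_intensity_pct,operatory_max_intensity_pct,operatory_max_site,clinician_frequency_n,clinician_mean_intensity_pct,clinician_max_intensity_pct,clinician_max_site,assistant_frequency_n,assistant_mean_intensity_pct,assistant_max_intensity_pct,assistant_max_site
A1,Occlusal cavity preparation of 36; veneer preparation of 31 and 21 (air turbine),closed,20 minutes,HVS and SE,10,1.56,2.64,Patient,7,4.24,51.94,Visor front,2,0.22,3.42,Visor front
A2,Occlusal cavity preparation of 36; veneer preparation of 31 and 21 (air turbine),closed,20 minutes,"EOS, HVS and SE",10,0.61,10.49,Patient,6,2.31,19.11,Left shoe,2,0.04,0.53,Left shoe
A3,Occlusal cavity preparation of 36; veneer preparation of 31 and 21 (air turbine),open,20 minutes,HVS and SE,11,9.49,94.12,Patient,6,0.22,1.47,Visor front,4,3.20,44.24,Visor front
A4,Occlusal cavity preparation of 36; veneer preparation of 31 and 21 (air turbine),open,20 minutes,"EOS, HVS and SE",6,1.7,5.24,Patient,4,0.30,3.55,Visor front,4,0.36,4.20,Left forearm
A5,Occlusal cavity preparation of 36; veneer preparation of 31 and 21 (air turbine),open,20 minutes,HVS and SE (short visor),7,15.87,98.88,Patient,5,0.31,1.82,Chest,6,0.39,1.82,Chest
A6,Occlusal cavity preparation of 36; veneer preparation of 31 and 21 (air turbine),open,20 minutes,"EOS, HVS and SE (short visor)",6,1.33,3.58,Patient,7,0.40,2.08,Visor front,5,0.17,1.67,Right forearm
B1,Labial veneer and palatal access cavity preparation of 21 (air turbine),closed,10 minutes,"RD, HVS and SE",9,0.34,6.46,Patient,5,1.57,11.48,Chest,3,0.15,1.45,Head back
B2,Labial veneer and palatal access cavity preparation of 21 (air turbine),closed,10 minutes,"RD, EOS, HVS and SE",7,0.11,0.99,Site 18,6,0.82,5.49,Visor left,2,0.06,0.62,Left shoe
C1,Occlusal cavity preparation of 36 (air turbine),closed,5 minutes,HVS,8,3.28,88.8,Patient,6,0.80,4.80,Chest,4,0.60,7.01,Right forearm
C2,Occlusal cavity preparation of 36 (air turbine),closed,5 minutes,EOS and HVS,6,1.91,69.01,Site 24,6,1.38,13.17,Chest,3,0.28,3.80,Left forearm
C3,Occlusal cavity preparation of 36 (air turbine),closed,5 minutes,EOS and SE,4,0.19,4.72,Patient,1,0.06,1.12,Mask,1,0.13,2.29,Left forearm
C4,Occlusal cavity preparation of 36 (air turbine),closed,5 minutes,No suction,10,2.53,56.93,Patient,7,3.24,23.28,Chest,,,,
D1,Occlusal cavity preparation of 46 (air turbine),open,5 minutes,HVS and SE,3,1.27,2.87,Patient,4,0.12,0.84,Right forearm,3,0.11,0.72,Visor front
D2,Occlusal cavity preparation of 46 (air turbine),closed,5 minutes,"RD, HVS and SE",2,0.03,0.83,Site 18,5,0.34,2.11,Chest,3,0.17,2.04,Right forearm
D3,Occlusal cavity preparation of 46 (air turbine),closed,5 minutes,"RD, EOS, HVS and SE",4,0.18,4.29,Patient,4,0.19,1.04,Left forearm,3,0.13,0.95,Right forearm
E1,Full mouth debridement (ultrasonic scaler),closed,7 minutes,"70% speed, HVS and SE",0,0.00,0.00,,2,0.07,0.73,Chest,1,0.03,0.57,Right shoe
E2,Full mouth debridement (ultrasonic scaler),closed,7 minutes,"70% speed, EOS, HVS and SE",4,0.05,1.19,Patient,2,0.05,0.71,Chest,0,0.00,0.00,
E3,Full mouth debridement (ultrasonic scaler),closed,7 minutes,"100% speed, HVS and SE",2,0.32,10.26,Nurse's chair,1,0.10,1.72,Chest,0,0.00,0.00,
E4,Full mouth debridement (ultrasonic scaler),closed,7 minutes,"100% speed, EOS, HVS and SE",2,0.14,5.96,Patient,1,0.05,0.83,Chest,0,0.00,0.00,
E5,Full mouth debridement (ultrasonic scaler),closed,7 minutes,"100% speed, SE",4,1.68,73.59,Patient,3,0.17,1.46,Right forearm,,,,
E6,Full mouth debridement (ultrasonic scaler),closed,7 minutes,"100% speed, EOS and SE (no HVS)",1,0.21,9.33,Patient,2,0.28,3.76,Right shoe,,,,
E7,Full mouth debridement (ultrasonic scaler),open,7 minutes,"100% speed, HVS and SE",3,0.02,1.26,Patient,2,0.07,0.79,Head top,0,0.00,0.00,
E8,Full mouth debridement (ultrasonic scaler),open,7 minutes,"100% speed, EOS and SE (no HVS)",1,0.01,0.73,Site 71,4,0.22,1.86,Left shoe,,,,
F1,Triple air syringe into 36 occlusal cavity,closed,5 minutes continuously,HVS,5,0.16,3.19,Bracket table,4,0.47,3.78,Right shoe,2,0.05,0.64,Visor front
F2,Triple air syringe into 36 occlusal cavity,closed,5 minutes continuously,"EOS, HVS and SE",4,0.05,0.77,Site 25,3,0.14,1.30,Head back,4,0.24,1.65,Right forearm
G1,Surgical sectioning of 37 and 38,closed,10 minutes,Surgical suction and SE,1,2.14,96.45,Patient,1,0.15,2.74,Chest,3,5.44,45.23,Chest
G2,Surgical sectioning of 37 and 38,closed,10 minutes,Surgical suction,1,1.35,8.71,Patient,1,1.36,24.52,Chest,4,7.30,71.07,Chest
G3,Surgical sectioning of 37 and 38,closed,10 minutes,EOS and surgical suction,1,1.66,74.7,Patient,2,0.28,4.10,Visor right,3,1.63,21.80,Chest
H1,Surgical sectioning of 47 and 48,closed,10 minutes,Surgical suction and SE,1,2.01,90.24,Patient,2,0.09,1.13,Chest,5,3.51,53.13,Chest
H2,Surgical sectioning of 47 and 48,closed,10 minutes,Surgical suction only,1,0.77,34.71,Patient,2,0.08,1.13,Visor front,6,3.26,56.15,Chest
I1,Implant osteotomy preparation of 36,closed,Sequential implant drills 2.2/2.8/3.5 mm,Surgical suction,1,0.04,1.72,Patient,0,0.00,0.00,,3,0.50,4.17,Visor front
J1,Implant osteotomy preparation of 46,closed,Sequential implant drills 2.2/2.8/3.5 mm,Surgical suction,0,0,0,,1,0.04,0.64,Chest,2,0.08,0.91,Chest
J2,Implant osteotomy preparation of 46,closed,Sequential implant drills 2.2/2.8/3.5 mm,Surgical suction and SE,1,2,90.15,Patient,0,0.00,0.00,,4,2.77,46.55,Chest
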