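subject_id,gestational_age_weeks,gestational_age_extra_days,csf_threshold,mri_volume_mL,mri_weight_g,manual_weight_g,autopsy_weight_g
121,39,0,700,361.74,390.67,390.40,388.00
149,34,2,700,267.79,289.22,N/A,N/A
196,32,2,800,160.66,173.52,172.59,181.00
210,38,6,600,354.74,383.12,N/A,391.00
214,37,2,550,298.07,321.92,N/A,328.00
230,41,6,450,370.73,400.39,N/A,401.00
246,32,6,530,208.06,224.70,225.54,223.70
282,30,5,500,146.96,158.72,N/A,N/A
299,44,0,300,408.43,441.11,438.00,447.00
330,35,6,800,264.72,285.90,N/A,292.00
339,36,2,800,339.31,366.45,365.05,N/A
343,34,1,350,247.69,267.50,N/A,275.00
379,38,5,290,357.13,385.70,N/A,386.13
384,39,4,300,366.63,395.96,N/A,389.80
388,38,0,390,439.41,474.56,469.56,N/A
391,33,0,550,213.39,230.46,231.59,226.00
396,29,0,700,113.70,122.80,122.22,128.00
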