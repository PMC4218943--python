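subject_id,gestational_age_weeks,postnatal_age_days,csf_threshold,mri_volume_mL,mri_weight_g,manual_weight_g,autopsy_weight_g
193,40,21,600,418.15,451.61,446.08,457.0
194,39,1,600,418.56,452.05,446.46,462.5
256,38,1,800,360.43,389.27,N/A,433.0
259,29,120,400,413.45,446.52,442.92,456.7
262,37,3,500,338.13,365.18,N/A,368.0
274,40,2,600,430.50,481.29,N/A,N/A
276,41,1,600,333.32,359.99,N/A,367.0
293,35,10,600,329.07,355.40,350.62,360.0
300,40,1,400,388.61,419.70,N/A,420.0
306,37,1,500,287.15,345.49,309.86,N/A
313,37,3,800,310.26,335.08,N/A,360.0
315,40,3,900,321.41,347.13,347.30,409.0
318,40,2,400,313.07,338.12,N/A,368.0
325,40,30,500,586.24,633.14,627.79,635.0
356,40,1,600,428.28,462.54,N/A,445.9
368,35,5,600,345.69,373.35,N/A,363.8
386,40,30,700,501.73,541.87,534.37,609.0
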