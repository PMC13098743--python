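# Reference transfusion-cohort fixture: demographic, clinical and blood-gas
# records for the 15 critically ill subjects whose session structure and
# blood-gas magnitudes the synthetic generator emulates.
# subject 3 was excluded from analysis (poor optical SNR at both sites);
# subject 2 has no blood-gas data (NA). hgb in g/dL, hct in %, age in years,
# rbc_storage in days since donation.
subject_id,sex,age_years,polytrauma,tbi,gcs,lesion_type,etiology,hgb_pre_gdl,hgb_post_gdl,hct_pre_pct,hct_post_pct,rbc_storage_days,included
1,F,21,yes,yes,4,DI-IV,traffic accident (motorcycle),8.5,9.6,26,29,30,yes
2,M,18,yes,yes,5,EML-epidural,traffic accident (car),,,,,16,yes
3,M,55,no,no,15,not applicable,suicide attempt (severe burns),7.6,8.9,23,27,21,no
4,M,44,yes,yes,14,DI-I,traffic accident (motorcycle),8.2,8.9,25,27,16,yes
5,M,16,yes,yes,7,DI-II,traffic accident (motorcycle),8,9.2,24,28,17,yes
6,M,24,yes,yes,15,DI-I,traffic accident (motorcycle),8.2,8.9,25,27,26,yes
7,M,70,no,no,15,not applicable,stroke,9.2,9.8,28,29,29,yes
8,F,72,yes,yes,15,DI-I,fall from height >3 m,7.6,8.7,23,26,25,yes
9,M,22,yes,yes,11,EML-subdural,fall from height >3 m,8.9,10.5,27,32,21,yes
10,M,50,yes,yes,14,DI-I,traffic accident (motorcycle),7.8,8.9,23,27,25,yes
11,F,65,no,no,15,not applicable,stroke,7.9,9,24,27,21,yes
12,M,51,no,no,15,not applicable,cerebral hematoma,7.8,8.8,23,26,21,yes
13,M,27,yes,yes,6,DI-I,hit by a train,7.9,8.7,24,26,20,yes
14,M,44,yes,no,15,not applicable,traffic accident (motorcycle),7.6,8.4,23,25,17,yes
15,M,26,no,no,15,not applicable,severe burns,8,9.1,24,27,12,yes
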