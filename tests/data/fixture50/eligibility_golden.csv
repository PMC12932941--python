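case_id,included,majors_met,minors_met,excluded,exclusions,evaluated_at,obstructive_restrictive_lung_disease,acute_respiratory_infection,obstructive_sleep_apnea,low_preop_spo2,airway_pathology_history,bmi_over_40,multiple_intubation_attempts,long_surgery,high_risk_surgical_site,bmi_over_35,low_hemoglobin
C000000,True,1,1,False,,2023-05-21T14:15:00,False,False,False,False,False,True,False,False,False,True,False
C000001,True,0,2,False,,2023-05-07T12:15:00,False,False,False,False,False,False,False,True,True,False,False
C000002,True,1,1,True,age_lt_18,2023-09-06T08:00:00,False,False,True,False,False,False,False,True,False,False,False
C000003,True,1,1,False,,2023-09-30T09:00:00,False,False,True,False,False,False,False,True,False,False,False
C000004,False,0,0,True,direct_icu_admission;planned_postop_intubation,2023-02-05T09:30:00,False,False,False,False,False,False,False,False,False,False,False
C000005,False,0,1,False,,2023-08-24T12:15:00,False,False,False,False,False,False,False,False,True,False,False
C000006,False,0,1,False,,2023-10-18T12:00:00,False,False,False,False,False,False,False,True,False,False,False
C000007,False,0,0,False,,2023-07-16T10:00:00,False,False,False,False,False,False,False,False,False,False,False
C000008,True,1,1,False,,2024-07-21T10:30:00,True,False,False,False,False,False,False,False,False,False,True
C000009,True,1,0,False,,2024-01-07T13:45:00,True,False,False,False,False,False,False,False,False,False,False
C000010,False,0,1,True,emergency,2023-07-14T12:30:00,False,False,False,False,False,False,False,True,False,False,False
C000011,False,0,1,False,,2023-11-12T14:00:00,False,False,False,False,False,False,False,True,False,False,False
C000012,False,0,1,True,emergency,2023-09-12T12:00:00,False,False,False,False,False,False,False,True,False,False,False
C000013,False,0,0,False,,2023-05-21T13:00:00,False,False,False,False,False,False,False,False,False,False,False
C000014,False,0,0,False,,2024-06-15T14:15:00,False,False,False,False,False,False,False,False,False,False,False
C000015,False,0,0,False,,2023-08-01T10:45:00,False,False,False,False,False,False,False,False,False,False,False
C000016,True,2,1,False,,2023-10-01T14:15:00,True,False,False,False,False,True,False,False,False,True,False
C000017,False,0,1,False,,2024-08-20T10:30:00,False,False,False,False,False,False,False,False,False,True,False
C000018,False,0,0,False,,2023-05-01T12:00:00,False,False,False,False,False,False,False,False,False,False,False
C000019,True,2,2,False,,2023-04-25T09:45:00,False,True,True,False,False,False,False,True,False,False,True
C000020,False,0,0,False,,2024-04-21T13:00:00,False,False,False,False,False,False,False,False,False,False,False
C000021,False,0,1,True,direct_icu_admission,2023-04-13T08:45:00,False,False,False,False,False,False,False,True,False,False,False
C000022,False,0,1,False,,2023-11-20T13:45:00,False,False,False,False,False,False,False,True,False,False,False
C000023,False,0,0,False,,2024-02-03T13:45:00,False,False,False,False,False,False,False,False,False,False,False
C000024,False,0,1,False,,2023-01-26T08:15:00,False,False,False,False,False,False,False,False,False,True,False
C000025,False,0,1,False,,2024-01-24T09:15:00,False,False,False,False,False,False,True,False,False,False,False
C000026,True,2,0,False,,2023-11-30T08:45:00,True,True,False,False,False,False,False,False,False,False,False
C000027,False,0,0,False,,2023-07-13T13:45:00,False,False,False,False,False,False,False,False,False,False,False
C000028,True,1,3,False,,2023-08-04T10:45:00,False,False,True,False,False,False,False,True,True,False,True
C000029,True,2,1,False,,2023-09-18T10:15:00,False,False,True,False,False,True,False,False,False,True,False
C000030,False,0,1,False,,2023-10-09T11:00:00,False,False,False,False,False,False,False,False,True,False,False
C000031,False,0,1,False,,2024-08-04T12:30:00,False,False,False,False,False,False,False,True,False,False,False
C000032,True,0,3,True,direct_icu_admission,2023-04-04T12:30:00,False,False,False,False,False,False,False,True,True,True,False
C000033,False,0,1,False,,2023-04-07T11:15:00,False,False,False,False,False,False,False,False,True,False,False
C000034,True,2,2,False,,2023-11-16T14:00:00,False,False,True,False,False,True,False,False,True,True,False
C000035,True,0,2,False,,2024-02-07T13:45:00,False,False,False,False,False,False,False,True,True,False,False
C000036,False,0,1,False,,2024-08-03T09:00:00,False,False,False,False,False,False,False,True,False,False,False
C000037,False,0,1,False,,2023-02-01T14:45:00,False,False,False,False,False,False,False,True,False,False,False
C000038,False,0,0,False,,2023-12-06T11:00:00,False,False,False,False,False,False,False,False,False,False,False
C000039,True,1,2,False,,2024-05-21T11:30:00,True,False,False,False,False,False,False,True,True,False,False
C000040,True,1,1,False,,2023-11-12T10:30:00,False,False,False,False,False,True,False,False,False,True,False
C000041,False,0,0,False,,2024-02-11T11:00:00,False,False,False,False,False,False,False,False,False,False,False
C000042,True,1,1,False,,2023-02-09T08:30:00,False,False,False,True,False,False,False,False,False,True,False
C000043,False,0,0,False,,2023-11-24T09:30:00,False,False,False,False,False,False,False,False,False,False,False
C000044,True,1,1,True,gfr_lt_30,2023-10-21T13:30:00,False,False,False,True,False,False,False,True,False,False,False
C000045,True,2,1,False,,2023-11-12T14:30:00,False,False,True,False,False,True,False,False,False,True,False
C000046,False,0,1,False,,2023-10-13T11:30:00,False,False,False,False,False,False,False,False,True,False,False
C000047,False,0,0,False,,2023-01-28T08:15:00,False,False,False,False,False,False,False,False,False,False,False
C000048,False,0,1,False,,2023-02-12T08:00:00,False,False,False,False,False,False,False,False,True,False,False
C000049,True,1,0,False,,2023-11-10T12:15:00,False,False,True,False,False,False,False,False,False,False,False
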