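id,parity,presentation,engaged,palpable_head,efw_ge_10th,mvp_ge_4cm,placenta_posterior,tocolysis,success
S001,multiparous,transverse,0,1,1,1,0,0,1
S002,multiparous,transverse,0,1,1,1,0,0,1
S003,multiparous,transverse,0,1,1,1,0,0,1
S004,multiparous,transverse,0,1,1,1,0,0,1
S005,multiparous,transverse,0,1,1,1,0,0,1
S006,multiparous,transverse,0,1,1,1,0,0,1
S007,multiparous,transverse,0,1,1,1,0,0,1
S008,nulliparous,complete_breech,1,1,1,1,0,0,1
S009,nulliparous,complete_breech,1,1,1,1,0,0,1
S010,nulliparous,complete_breech,1,1,0,1,0,1,1
S011,nulliparous,complete_breech,1,1,0,1,0,1,1
S012,nulliparous,complete_breech,1,1,0,1,0,1,1
S013,nulliparous,complete_breech,1,1,0,1,0,1,1
S014,nulliparous,complete_breech,1,1,0,1,1,1,1
S015,nulliparous,complete_breech,1,1,0,1,1,1,1
S016,nulliparous,complete_breech,1,1,0,1,1,1,1
S017,nulliparous,complete_breech,1,1,0,1,1,1,1
S018,nulliparous,complete_breech,1,1,0,1,1,1,1
S019,nulliparous,frank_breech,1,1,0,1,1,1,1
S020,nulliparous,frank_breech,1,1,0,1,1,1,1
S021,nulliparous,frank_breech,1,1,0,1,1,1,1
S022,nulliparous,frank_breech,1,1,0,1,1,1,1
S023,nulliparous,frank_breech,1,1,0,1,1,1,1
S024,nulliparous,frank_breech,1,1,1,1,1,1,1
S025,nulliparous,frank_breech,1,1,1,1,1,1,1
S026,nulliparous,frank_breech,1,1,1,1,1,1,1
S027,nulliparous,frank_breech,1,1,1,1,1,1,1
S028,nulliparous,frank_breech,1,1,1,1,1,1,1
S029,nulliparous,frank_breech,1,1,1,1,1,1,1
S030,nulliparous,frank_breech,1,1,1,1,1,1,1
S031,nulliparous,frank_breech,1,1,1,1,1,1,1
S032,nulliparous,frank_breech,1,1,1,1,1,1,1
S033,nulliparous,frank_breech,1,1,1,1,1,1,1
S034,nulliparous,frank_breech,1,1,1,1,1,1,1
S035,multiparous,frank_breech,1,1,1,1,1,1,1
S036,multiparous,frank_breech,1,1,1,1,1,1,1
S037,multiparous,frank_breech,1,1,1,1,1,1,1
S038,multiparous,frank_breech,1,1,1,1,1,1,1
S039,multiparous,frank_breech,1,1,1,1,1,1,1
S040,multiparous,frank_breech,1,1,1,1,1,1,1
S041,multiparous,frank_breech,1,1,1,1,1,1,1
S042,multiparous,frank_breech,1,1,1,1,1,1,1
S043,multiparous,frank_breech,1,1,1,1,1,1,1
S044,multiparous,frank_breech,1,1,1,1,1,1,1
S045,multiparous,frank_breech,1,1,1,1,1,1,1
S046,multiparous,frank_breech,1,1,1,1,1,1,1
S047,multiparous,frank_breech,1,1,1,1,1,1,1
S048,multiparous,frank_breech,1,1,1,1,1,1,1
S049,multiparous,frank_breech,1,1,1,1,1,1,1
S050,multiparous,frank_breech,1,1,1,1,1,1,1
S051,multiparous,frank_breech,1,1,1,1,1,1,1
S052,multiparous,frank_breech,1,1,1,1,1,1,1
S053,multiparous,frank_breech,1,1,1,1,1,1,1
S054,multiparous,frank_breech,1,1,1,1,1,1,1
S055,multiparous,frank_breech,1,1,1,1,1,0,1
S056,multiparous,frank_breech,1,1,1,1,1,0,1
S057,multiparous,frank_breech,1,1,1,1,0,0,1
S058,multiparous,frank_breech,1,1,1,1,0,0,1
S059,multiparous,frank_breech,1,1,1,1,0,0,1
S060,multiparous,frank_breech,1,1,1,1,0,0,1
S061,multiparous,frank_breech,1,1,1,1,0,0,1
S062,multiparous,frank_breech,1,1,1,1,0,0,1
S063,multiparous,frank_breech,1,1,1,1,0,0,1
S064,multiparous,frank_breech,1,0,1,1,0,0,1
S065,multiparous,frank_breech,1,0,1,1,0,0,1
S066,multiparous,frank_breech,1,0,1,1,0,0,1
S067,multiparous,frank_breech,1,0,1,1,0,0,1
S068,multiparous,frank_breech,1,0,1,0,0,0,1
S069,multiparous,frank_breech,1,0,1,0,0,0,1
F001,nulliparous,transverse,0,1,1,1,0,0,0
F002,nulliparous,complete_breech,0,1,1,1,0,0,0
F003,nulliparous,complete_breech,0,1,1,1,0,0,0
F004,nulliparous,complete_breech,0,1,1,1,0,0,0
F005,nulliparous,complete_breech,0,1,0,1,0,1,0
F006,nulliparous,complete_breech,0,1,0,1,0,1,0
F007,nulliparous,frank_breech,0,0,0,1,1,1,0
F008,nulliparous,frank_breech,0,0,0,1,1,1,0
F009,nulliparous,frank_breech,0,0,0,1,1,1,0
F010,nulliparous,frank_breech,0,0,0,1,1,1,0
F011,nulliparous,frank_breech,0,0,1,1,1,1,0
F012,nulliparous,frank_breech,0,0,1,1,1,1,0
F013,nulliparous,frank_breech,0,0,1,1,0,1,0
F014,nulliparous,frank_breech,0,0,1,1,0,1,0
F015,nulliparous,frank_breech,0,0,1,1,0,1,0
F016,multiparous,frank_breech,0,0,1,1,0,1,0
F017,multiparous,frank_breech,0,0,1,1,0,1,0
F018,multiparous,frank_breech,0,0,1,1,0,1,0
F019,multiparous,frank_breech,0,0,1,1,0,1,0
F020,multiparous,frank_breech,0,0,1,0,0,1,0
F021,multiparous,frank_breech,0,0,1,0,0,1,0
F022,multiparous,frank_breech,0,0,1,0,0,1,0
F023,multiparous,frank_breech,0,0,1,0,0,1,0
F024,multiparous,frank_breech,0,0,1,0,0,1,0
F025,multiparous,frank_breech,0,0,1,0,0,0,0
F026,multiparous,frank_breech,0,0,1,0,0,0,0
F027,multiparous,frank_breech,0,0,1,0,0,0,0
F028,multiparous,frank_breech,0,0,1,0,0,0,0
F029,nulliparous,frank_breech,0,0,1,0,0,0,0
F030,nulliparous,frank_breech,1,0,1,0,0,0,0
F031,nulliparous,frank_breech,1,0,1,0,0,0,0
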