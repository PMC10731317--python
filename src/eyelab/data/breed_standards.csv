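# Stand-in breed-standard eye-colour table.
# Breed names are placeholders; per-registry totals and dark-recommended
# counts follow the AKC/KC registry summaries (AKC 77/82 dark, KC 76/82 dark).
breed,registry,eye_colour_recommendation
akc_breed_001,AKC,dark
akc_breed_002,AKC,dark
akc_breed_003,AKC,dark
akc_breed_004,AKC,dark
akc_breed_005,AKC,dark
akc_breed_006,AKC,dark
akc_breed_007,AKC,dark
akc_breed_008,AKC,dark
akc_breed_009,AKC,dark
akc_breed_010,AKC,dark
akc_breed_011,AKC,dark
akc_breed_012,AKC,dark
akc_breed_013,AKC,dark
akc_breed_014,AKC,dark
akc_breed_015,AKC,dark
akc_breed_016,AKC,dark
akc_breed_017,AKC,dark
akc_breed_018,AKC,dark
akc_breed_019,AKC,dark
akc_breed_020,AKC,dark
akc_breed_021,AKC,dark
akc_breed_022,AKC,dark
akc_breed_023,AKC,dark
akc_breed_024,AKC,dark
akc_breed_025,AKC,dark
akc_breed_026,AKC,dark
akc_breed_027,AKC,dark
akc_breed_028,AKC,dark
akc_breed_029,AKC,dark
akc_breed_030,AKC,dark
akc_breed_031,AKC,dark
akc_breed_032,AKC,dark
akc_breed_033,AKC,dark
akc_breed_034,AKC,dark
akc_breed_035,AKC,dark
akc_breed_036,AKC,dark
akc_breed_037,AKC,dark
akc_breed_038,AKC,dark
akc_breed_039,AKC,dark
akc_breed_040,AKC,dark
akc_breed_041,AKC,dark
akc_breed_042,AKC,dark
akc_breed_043,AKC,dark
akc_breed_044,AKC,dark
akc_breed_045,AKC,dark
akc_breed_046,AKC,dark
akc_breed_047,AKC,dark
akc_breed_048,AKC,dark
akc_breed_049,AKC,dark
akc_breed_050,AKC,dark
akc_breed_051,AKC,dark
akc_breed_052,AKC,dark
akc_breed_053,AKC,dark
akc_breed_054,AKC,dark
akc_breed_055,AKC,dark
akc_breed_056,AKC,dark
akc_breed_057,AKC,dark
akc_breed_058,AKC,dark
akc_breed_059,AKC,dark
akc_breed_060,AKC,dark
akc_breed_061,AKC,dark
akc_breed_062,AKC,dark
akc_breed_063,AKC,dark
akc_breed_064,AKC,dark
akc_breed_065,AKC,dark
akc_breed_066,AKC,dark
akc_breed_067,AKC,dark
akc_breed_068,AKC,dark
akc_breed_069,AKC,dark
akc_breed_070,AKC,dark
akc_breed_071,AKC,dark
akc_breed_072,AKC,dark
akc_breed_073,AKC,dark
akc_breed_074,AKC,dark
akc_breed_075,AKC,dark
akc_breed_076,AKC,dark
akc_breed_077,AKC,dark
akc_breed_078,AKC,other
akc_breed_079,AKC,other
akc_breed_080,AKC,other
akc_breed_081,AKC,other
akc_breed_082,AKC,other
kc_breed_001,KC,dark
kc_breed_002,KC,dark
kc_breed_003,KC,dark
kc_breed_004,KC,dark
kc_breed_005,KC,dark
kc_breed_006,KC,dark
kc_breed_007,KC,dark
kc_breed_008,KC,dark
kc_breed_009,KC,dark
kc_breed_010,KC,dark
kc_breed_011,KC,dark
kc_breed_012,KC,dark
kc_breed_013,KC,dark
kc_breed_014,KC,dark
kc_breed_015,KC,dark
kc_breed_016,KC,dark
kc_breed_017,KC,dark
kc_breed_018,KC,dark
kc_breed_019,KC,dark
kc_breed_020,KC,dark
kc_breed_021,KC,dark
kc_breed_022,KC,dark
kc_breed_023,KC,dark
kc_breed_024,KC,dark
kc_breed_025,KC,dark
kc_breed_026,KC,dark
kc_breed_027,KC,dark
kc_breed_028,KC,dark
kc_breed_029,KC,dark
kc_breed_030,KC,dark
kc_breed_031,KC,dark
kc_breed_032,KC,dark
kc_breed_033,KC,dark
kc_breed_034,KC,dark
kc_breed_035,KC,dark
kc_breed_036,KC,dark
kc_breed_037,KC,dark
kc_breed_038,KC,dark
kc_breed_039,KC,dark
kc_breed_040,KC,dark
kc_breed_041,KC,dark
kc_breed_042,KC,dark
kc_breed_043,KC,dark
kc_breed_044,KC,dark
kc_breed_045,KC,dark
kc_breed_046,KC,dark
kc_breed_047,KC,dark
kc_breed_048,KC,dark
kc_breed_049,KC,dark
kc_breed_050,KC,dark
kc_breed_051,KC,dark
kc_breed_052,KC,dark
kc_breed_053,KC,dark
kc_breed_054,KC,dark
kc_breed_055,KC,dark
kc_breed_056,KC,dark
kc_breed_057,KC,dark
kc_breed_058,KC,dark
kc_breed_059,KC,dark
kc_breed_060,KC,dark
kc_breed_061,KC,dark
kc_breed_062,KC,dark
kc_breed_063,KC,dark
kc_breed_064,KC,dark
kc_breed_065,KC,dark
kc_breed_066,KC,dark
kc_breed_067,KC,dark
kc_breed_068,KC,dark
kc_breed_069,KC,dark
kc_breed_070,KC,dark
kc_breed_071,KC,dark
kc_breed_072,KC,dark
kc_breed_073,KC,dark
kc_breed_074,KC,dark
kc_breed_075,KC,dark
kc_breed_076,KC,dark
kc_breed_077,KC,other
kc_breed_078,KC,other
kc_breed_079,KC,other
kc_breed_080,KC,other
kc_breed_081,KC,other
kc_breed_082,KC,other
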