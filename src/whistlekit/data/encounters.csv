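date,latitude,longitude,encounter_min,n_recordings,recording_min
2023-07-20,32.33448,-17.05021,125,8,110
2023-07-26,32.67354,-17.20696,243,7,56
2023-07-28,32.57956,-17.11244,138,8,96
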