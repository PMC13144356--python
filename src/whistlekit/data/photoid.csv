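date,group_size,n_calves,n_identified,n_seen_one_event,n_seen_two_events,n_seen_three_events
2023-07-20,40,1,12,3,3,6
2023-07-26,45,2,19,9,4,6
2023-07-28,40,2,18,5,7,6
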