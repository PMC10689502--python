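guild	share
m1	0.5494505494505495
m2	0.19780219780219782
saob	0.2527472527472528
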