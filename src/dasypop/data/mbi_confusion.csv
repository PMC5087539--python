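predicted,actual_building,actual_nonbuilding
building,158,57
nonbuilding,29,330
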