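# Published cMyC 0/1h rule set: single-sample rule-out irrespective of
# chest-pain onset; signed 0/1 h changes.
name: cmyc-0/1h
marker: cmyc
ruleout_single_0h: 10.0
ruleout_paired_0h: 18.0
ruleout_paired_delta: 4.0
rulein_0h: 140.0
rulein_delta: 15.0
delta_convention: signed
ruleout_single_requires_onset_gt: null
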