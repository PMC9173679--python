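# ESC-style hs-cTnT (Elecsys) 0/1h rule-set TEMPLATE.
#
# The numeric thresholds below are the widely circulated 2020 ESC guideline
# values for the Elecsys hs-cTnT assay.  VERIFY THEM against the current
# guideline before clinical or analytical use — this package treats them as
# user-supplied configuration, not as validated constants.
#
# The single-sample rule-out is gated on chest-pain onset > 3 h; 0/1 h
# changes are unsigned magnitudes.
name: esc-hstnt-0/1h
marker: tnt
ruleout_single_0h: 5.0
ruleout_paired_0h: 12.0
ruleout_paired_delta: 3.0
rulein_0h: 52.0
rulein_delta: 5.0
delta_convention: unsigned
ruleout_single_requires_onset_gt: 3.0
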