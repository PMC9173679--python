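# ESC-style hs-cTnI (Architect) 0/1h rule-set TEMPLATE.
#
# The numeric thresholds below are the widely circulated 2020 ESC guideline
# values for the Architect hs-cTnI assay.  VERIFY THEM against the current
# guideline before clinical or analytical use — this package treats them as
# user-supplied configuration, not as validated constants.
name: esc-hstni-0/1h
marker: tni
ruleout_single_0h: 4.0
ruleout_paired_0h: 5.0
ruleout_paired_delta: 2.0
rulein_0h: 64.0
rulein_delta: 6.0
delta_convention: unsigned
ruleout_single_requires_onset_gt: 3.0
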