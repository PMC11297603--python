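# PLACEHOLDER uniform EZ Metric weights.
# The published weighting scheme lives in external supplementary material and
# is supplied by the user; this file gives every endpoint weight 1.0 purely so
# the ezscore command can be exercised end to end. Endpoint roster: 4 calls at
# 24 hpf and 17 at 120 hpf.
MO24:   {weight: 1.0, group: 24hpf}
DP24:   {weight: 1.0, group: 24hpf}
SM24:   {weight: 1.0, group: 24hpf}
NC24:   {weight: 1.0, group: 24hpf}
MORT:   {weight: 1.0, group: 120hpf}
YSE:    {weight: 1.0, group: 120hpf}
AXIS:   {weight: 1.0, group: 120hpf}
EYE:    {weight: 1.0, group: 120hpf}
SNOU:   {weight: 1.0, group: 120hpf}
JAW:    {weight: 1.0, group: 120hpf}
OTIC:   {weight: 1.0, group: 120hpf}
PE:     {weight: 1.0, group: 120hpf}
BRAI:   {weight: 1.0, group: 120hpf}
SOMI:   {weight: 1.0, group: 120hpf}
PFIN:   {weight: 1.0, group: 120hpf}
CFIN:   {weight: 1.0, group: 120hpf}
PIG:    {weight: 1.0, group: 120hpf}
CIRC:   {weight: 1.0, group: 120hpf}
TRUN:   {weight: 1.0, group: 120hpf}
SWIM:   {weight: 1.0, group: 120hpf}
TR:     {weight: 1.0, group: 120hpf}
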