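group,sink,members
g+/+,yg14,yg12 yg14 yg19 yg58
g+/−,yg17,yg17 yg18 yg25
g−/+,yg31,yg6 yg31 yg35 yg52 yg57 yg67
g−/−,yg32,yg27 yg32 yg33 yg51 yg56 yg63 yg71
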