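XScale: 0.45
YScale: 560
DtoGDelay: 4
DtoGFract: 0.7
DtoGProb: 0.8
DiffGRatio: 0.05
GtoCDelay: 0
GtoCFract: 0.1
GtoCProb: 0.1
GAtoPDelay: 0
GAtoPFract: 0.7
GAtoPProb: 0.5
GBtoPDelay: 9
GBtoPFract: 0.45
GBtoPProb: 0.5
GCtoPDelay: 9
GCtoPFract: 0.6
GCtoPProb: 0.6
PtoEDelay: 0
PtoEFract: 0.55
PtoEProb: 0.7
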