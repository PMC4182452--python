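XScale: 0.45
YScale: 6800
DtoGDelay: 1
DtoGFract: 0.8
DtoGProb: 0.9
DiffGRatio: 0.6
GtoCDelay: 0
GtoCFract: 0.2
GtoCProb: 0.2
GAtoPDelay: 0
GAtoPFract: 0.6
GAtoPProb: 0.5
GBtoPDelay: 6
GBtoPFract: 0.8
GBtoPProb: 0.5
GCtoPDelay: 8
GCtoPFract: 0.8
GCtoPProb: 0.7
PtoEDelay: 0
PtoEFract: 0.35
PtoEProb: 0.5
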