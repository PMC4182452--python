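XScale: 0.45
YScale: 2800
DtoGDelay: 2
DtoGFract: 0.8
DtoGProb: 0.9
DiffGRatio: 0.2
GtoCDelay: 0
GtoCFract: 0.2
GtoCProb: 0.3
GAtoPDelay: 0
GAtoPFract: 0.6
GAtoPProb: 0.7
GBtoPDelay: 9
GBtoPFract: 0.75
GBtoPProb: 0.8
GCtoPDelay: 5
GCtoPFract: 0.8
GCtoPProb: 0.7
PtoEDelay: 0
PtoEFract: 0.8
PtoEProb: 0.6
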