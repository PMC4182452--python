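XScale: 0.45
YScale: 6200
DtoGDelay: 0
DtoGFract: 0.6
DtoGProb: 0.6
DiffGRatio: 0.05
GtoCDelay: 0
GtoCFract: 0.2
GtoCProb: 0.2
GAtoPDelay: 0
GAtoPFract: 0.6
GAtoPProb: 0.8
GBtoPDelay: 7
GBtoPFract: 0.5
GBtoPProb: 0.5
GCtoPDelay: 4
GCtoPFract: 0.8
GCtoPProb: 0.7
PtoEDelay: 0
PtoEFract: 0.3
PtoEProb: 0.45
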