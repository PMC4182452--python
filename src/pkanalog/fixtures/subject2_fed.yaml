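XScale: 0.45
YScale: 6200
DtoGDelay: 1
DtoGFract: 0.7
DtoGProb: 0.8
DiffGRatio: 0.2
GtoCDelay: 0
GtoCFract: 0.2
GtoCProb: 0.4
GAtoPDelay: 0
GAtoPFract: 0.9
GAtoPProb: 0.9
GBtoPDelay: 5
GBtoPFract: 0.8
GBtoPProb: 0.7
GCtoPDelay: 9
GCtoPFract: 0.9
GCtoPProb: 0.7
PtoEDelay: 0
PtoEFract: 0.3
PtoEProb: 0.35
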