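XScale: 0.45
YScale: 3100
DtoGDelay: 3
DtoGFract: 0.5
DtoGProb: 0.5
DiffGRatio: 0.3
GtoCDelay: 0
GtoCFract: 0.1
GtoCProb: 0.2
GAtoPDelay: 0
GAtoPFract: 0.6
GAtoPProb: 0.5
GBtoPDelay: 7
GBtoPFract: 0.8
GBtoPProb: 0.5
GCtoPDelay: 12
GCtoPFract: 0.8
GCtoPProb: 0.8
PtoEDelay: 0
PtoEFract: 0.4
PtoEProb: 0.8
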