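XScale: 0.45
YScale: 6800
DtoGDelay: 0
DtoGFract: 0.3
DtoGProb: 0.5
DiffGRatio: 0.8
GtoCDelay: 0
GtoCFract: 0.3
GtoCProb: 0.2
GAtoPDelay: 0
GAtoPFract: 0.6
GAtoPProb: 0.5
GBtoPDelay: 14
GBtoPFract: 0.8
GBtoPProb: 0.5
GCtoPDelay: 8
GCtoPFract: 0.8
GCtoPProb: 0.8
PtoEDelay: 0
PtoEFract: 0.3
PtoEProb: 0.8
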