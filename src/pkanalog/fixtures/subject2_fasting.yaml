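XScale: 0.45
YScale: 6800
DtoGDelay: 1
DtoGFract: 0.3
DtoGProb: 0.5
DiffGRatio: 1
GtoCDelay: 0
GtoCFract: 0
GtoCProb: 0
GAtoPDelay: 0
GAtoPFract: 0.9
GAtoPProb: 0.9
GBtoPDelay: 6
GBtoPFract: 0.3
GBtoPProb: 0.3
GCtoPDelay: 0
GCtoPFract: 0
GCtoPProb: 0
PtoEDelay: 0
PtoEFract: 0.3
PtoEProb: 0.6
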