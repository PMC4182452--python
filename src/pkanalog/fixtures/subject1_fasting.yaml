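XScale: 0.45
YScale: 6800
DtoGDelay: 0
DtoGFract: 0.6
DtoGProb: 0.8
DiffGRatio: 0.15
GtoCDelay: 0
GtoCFract: 0.3
GtoCProb: 0.2
GAtoPDelay: 0
GAtoPFract: 0.9
GAtoPProb: 0.9
GBtoPDelay: 6
GBtoPFract: 0.3
GBtoPProb: 0.3
GCtoPDelay: 10
GCtoPFract: 0.35
GCtoPProb: 0.3
PtoEDelay: 0
PtoEFract: 0.35
PtoEProb: 0.8
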