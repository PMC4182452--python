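XScale: 0.45
YScale: 6800
DtoGDelay: 0
DtoGFract: 0.5
DtoGProb: 0.6
DiffGRatio: 0.7
GtoCDelay: 0
GtoCFract: 0.2
GtoCProb: 0.3
GAtoPDelay: 0
GAtoPFract: 0.6
GAtoPProb: 0.8
GBtoPDelay: 10
GBtoPFract: 0.8
GBtoPProb: 0.9
GCtoPDelay: 8
GCtoPFract: 0.9
GCtoPProb: 0.8
PtoEDelay: 0
PtoEFract: 0.33
PtoEProb: 0.7
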