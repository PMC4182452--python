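XScale: 0.45
YScale: 6200
DtoGDelay: 4
DtoGFract: 0.25
DtoGProb: 0.8
DiffGRatio: 0.25
GtoCDelay: 0
GtoCFract: 0.3
GtoCProb: 0.3
GAtoPDelay: 0
GAtoPFract: 0.9
GAtoPProb: 0.9
GBtoPDelay: 11
GBtoPFract: 0.5
GBtoPProb: 0.5
GCtoPDelay: 9
GCtoPFract: 0.5
GCtoPProb: 0.6
PtoEDelay: 0
PtoEFract: 0.2
PtoEProb: 0.8
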