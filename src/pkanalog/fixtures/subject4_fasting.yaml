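XScale: 0.45
YScale: 600
DtoGDelay: 3
DtoGFract: 0.7
DtoGProb: 0.8
DiffGRatio: 0.7
GtoCDelay: 0
GtoCFract: 0.2
GtoCProb: 0.2
GAtoPDelay: 0
GAtoPFract: 0.32
GAtoPProb: 0.5
GBtoPDelay: 7
GBtoPFract: 0.6
GBtoPProb: 0.5
GCtoPDelay: 8
GCtoPFract: 0.6
GCtoPProb: 0.6
PtoEDelay: 0
PtoEFract: 0.6
PtoEProb: 0.8
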