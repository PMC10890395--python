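{
 "temperature": 298.15,
 "pH": 7.4,
 "pMg": 3.0,
 "ionic_strength": 0.25
}
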