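archetype: ards
Au:
  value: 1.80944766118688
  unit: cmH2O.s/L
Ku:
  value: 3.1931429315062587
  unit: cmH2O.s2/L2
Kc:
  value: 0.750585679115209
  unit: cmH2O.s/L
Vcmax:
  value: 0.1667800374893624
  unit: L
As:
  value: 2.8185586418406716
  unit: cmH2O.s/L
Ks:
  value: -2.886777891577177
  unit: '-'
Bs:
  value: 1.1967828965694984
  unit: cmH2O.s/L
Vstar:
  value: 4.633219962510638
  unit: L
RV:
  value: 0.5
  unit: L
TLC:
  value: 4.8
  unit: L
Ac:
  value: 0.3251377442746241
  unit: 1/cmH2O
Bc:
  value: -3.180746117554481
  unit: cmH2O
Dc:
  value: 1.0
  unit: '-'
Acw:
  value: 6.898777805159306
  unit: cmH2O
Bcw:
  value: 7.710475857307084
  unit: cmH2O
Al:
  value: 4.633219962510638
  unit: L
Bl:
  value: 0.10182152615169543
  unit: 1/cmH2O
Dl:
  value: 15.429010605912008
  unit: cmH2O
Cve:
  value: 0.5
  unit: L/cmH2O
Rve:
  value: 1.5
  unit: cmH2O.s/L
Rd:
  value: 10000000.0
  unit: cmH2O.s/L
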