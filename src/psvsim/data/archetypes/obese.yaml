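archetype: obese
Au:
  value: 2.554514345205007
  unit: cmH2O.s/L
Ku:
  value: 10.94791862230717
  unit: cmH2O.s2/L2
Kc:
  value: 0.750585679115209
  unit: cmH2O.s/L
Vcmax:
  value: 0.1667800374893624
  unit: L
As:
  value: 1.1802888243905367
  unit: cmH2O.s/L
Ks:
  value: -2.886777891577177
  unit: '-'
Bs:
  value: 0.5885651953302111
  unit: cmH2O.s/L
Vstar:
  value: 4.933219962510638
  unit: L
RV:
  value: 0.5
  unit: L
TLC:
  value: 5.1
  unit: L
Ac:
  value: 0.25839158401476475
  unit: 1/cmH2O
Bc:
  value: -5.1644719281975044
  unit: cmH2O
Dc:
  value: 1.0
  unit: '-'
Acw:
  value: 4.442192097931859
  unit: cmH2O
Bcw:
  value: 4.709191454285325
  unit: cmH2O
Al:
  value: 4.933219962510638
  unit: L
Bl:
  value: 0.15314951949828987
  unit: 1/cmH2O
Dl:
  value: 13.8930342652855
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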