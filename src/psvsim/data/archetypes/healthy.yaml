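archetype: healthy
Au:
  value: 0.6893133947378589
  unit: cmH2O.s/L
Ku:
  value: 1.2164354024785744
  unit: cmH2O.s2/L2
Kc:
  value: 0.25019522637173636
  unit: cmH2O.s/L
Vcmax:
  value: 0.1667800374893624
  unit: L
As:
  value: 1.0314518231021716
  unit: cmH2O.s/L
Ks:
  value: -2.886777891577177
  unit: '-'
Bs:
  value: 0.358379785440547
  unit: cmH2O.s/L
Vstar:
  value: 5.833219962510638
  unit: L
RV:
  value: 1.2
  unit: L
TLC:
  value: 6.0
  unit: L
Ac:
  value: 0.44006065870344785
  unit: 1/cmH2O
Bc:
  value: -1.1752223736152345
  unit: cmH2O
Dc:
  value: 1.0
  unit: '-'
Acw:
  value: -1.0504503853523968
  unit: cmH2O
Bcw:
  value: 3.1293146500352935
  unit: cmH2O
Al:
  value: 5.833219962510638
  unit: L
Bl:
  value: 0.22243460840447837
  unit: 1/cmH2O
Dl:
  value: 6.6040755810969465
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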