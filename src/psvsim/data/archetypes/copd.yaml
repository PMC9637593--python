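archetype: copd
Au:
  value: 1.615578268916857
  unit: cmH2O.s/L
Ku:
  value: 2.8510204745591587
  unit: cmH2O.s2/L2
Kc:
  value: 1.2509761318586818
  unit: cmH2O.s/L
Vcmax:
  value: 0.1667800374893624
  unit: L
As:
  value: 7.108788191793276
  unit: cmH2O.s/L
Ks:
  value: -2.886777891577177
  unit: '-'
Bs:
  value: 1.6535406706250588
  unit: cmH2O.s/L
Vstar:
  value: 6.437719962510638
  unit: L
RV:
  value: 3.30225
  unit: L
TLC:
  value: 6.6045
  unit: L
Ac:
  value: 0.7862645668011469
  unit: 1/cmH2O
Bc:
  value: 6.323119269003657
  unit: cmH2O
Dc:
  value: 1.0
  unit: '-'
Acw:
  value: -2.0742100862232133
  unit: cmH2O
Bcw:
  value: 5.495171706501065
  unit: cmH2O
Al:
  value: 6.437719962510638
  unit: L
Bl:
  value: 0.10684750339458482
  unit: 1/cmH2O
Dl:
  value: 1.9839520421661891
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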