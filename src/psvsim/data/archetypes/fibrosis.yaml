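archetype: fibrosis
Au:
  value: 0.7237790644747519
  unit: cmH2O.s/L
Ku:
  value: 1.2772571726025033
  unit: cmH2O.s2/L2
Kc:
  value: 0.26270498769032313
  unit: cmH2O.s/L
Vcmax:
  value: 0.1667800374893624
  unit: L
As:
  value: 1.0631072233539447
  unit: cmH2O.s/L
Ks:
  value: -2.886777891577177
  unit: '-'
Bs:
  value: 0.37629877471257434
  unit: cmH2O.s/L
Vstar:
  value: 3.1332199625106374
  unit: L
RV:
  value: 1.1
  unit: L
TLC:
  value: 3.3
  unit: L
Ac:
  value: 0.35747870202011267
  unit: 1/cmH2O
Bc:
  value: -2.4859835266625803
  unit: cmH2O
Dc:
  value: 1.0
  unit: '-'
Acw:
  value: 3.803766611859989
  unit: cmH2O
Bcw:
  value: 8.43263083988839
  unit: cmH2O
Al:
  value: 3.1332199625106374
  unit: L
Bl:
  value: 0.06644584248101099
  unit: 1/cmH2O
Dl:
  value: 4.896545689900669
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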