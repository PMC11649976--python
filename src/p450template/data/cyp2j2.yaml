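name: CYP2J2
width_gauge: 1.5
facial_depth: 0.0
rear_depth: 1.5
vertices:
- label: '2'
  x: 0.0
  y: -0.577350269
  features:
  - in_site_of_oxidation
- label: '4'
  x: 1.0
  y: -0.577350269
  features:
  - in_site_of_oxidation
- label: '6'
  x: 2.0
  y: -0.577350269
  features: []
- label: eB3
  x: 3.0
  y: -0.577350269
  features: []
- label: '1'
  x: -0.5
  y: -0.288675135
  features: []
- label: '3'
  x: 0.5
  y: -0.288675135
  features:
  - in_site_of_oxidation
- label: '5'
  x: 1.5
  y: -0.288675135
  features: []
- label: '7'
  x: 2.5
  y: -0.288675135
  features: []
- label: eB2
  x: 3.5
  y: -0.288675135
  features: []
- label: eE2
  x: -1.5
  y: 0.288675135
  features:
  - under_shelf
- label: '9'
  x: -0.5
  y: 0.288675135
  features: []
- label: '11'
  x: 0.5
  y: 0.288675135
  features: []
- label: '13'
  x: 1.5
  y: 0.288675135
  features: []
- label: '15'
  x: 2.5
  y: 0.288675135
  features: []
- label: eB1
  x: 3.5
  y: 0.288675135
  features: []
- label: 11'
  x: -2.0
  y: 0.577350269
  features:
  - on_left_end
  - on_shelf_edge
- label: '8'
  x: -1.0
  y: 0.577350269
  features:
  - on_shelf_edge
- label: '10'
  x: 0.0
  y: 0.577350269
  features:
  - on_shelf_edge
- label: '12'
  x: 1.0
  y: 0.577350269
  features: []
- label: '14'
  x: 2.0
  y: 0.577350269
  features: []
- label: '16'
  x: 3.0
  y: 0.577350269
  features: []
- label: eC3
  x: 4.0
  y: 0.577350269
  features: []
- label: eE1
  x: -2.0
  y: 1.154700538
  features:
  - on_left_end
- label: '18'
  x: -1.0
  y: 1.154700538
  features: []
- label: '20'
  x: 0.0
  y: 1.154700538
  features: []
- label: '22'
  x: 1.0
  y: 1.154700538
  features: []
- label: '24'
  x: 2.0
  y: 1.154700538
  features: []
- label: '26'
  x: 3.0
  y: 1.154700538
  features: []
- label: eC2
  x: 4.0
  y: 1.154700538
  features: []
- label: eL2
  x: -2.5
  y: 1.443375673
  features:
  - on_left_end
- label: '17'
  x: -1.5
  y: 1.443375673
  features: []
- label: '19'
  x: -0.5
  y: 1.443375673
  features: []
- label: '21'
  x: 0.5
  y: 1.443375673
  features: []
- label: '23'
  x: 1.5
  y: 1.443375673
  features: []
- label: '25'
  x: 2.5
  y: 1.443375673
  features: []
- label: eC1
  x: 3.5
  y: 1.443375673
  features: []
- label: eL1
  x: -2.5
  y: 2.020725942
  features:
  - on_left_end
- label: '27'
  x: -1.5
  y: 2.020725942
  features: []
- label: '29'
  x: -0.5
  y: 2.020725942
  features: []
- label: '31'
  x: 0.5
  y: 2.020725942
  features: []
- label: '33'
  x: 1.5
  y: 2.020725942
  features: []
- label: '35'
  x: 2.5
  y: 2.020725942
  features: []
- label: eJ2
  x: 3.5
  y: 2.020725942
  features: []
- label: 27'
  x: -2.0
  y: 2.309401077
  features:
  - on_left_end
- label: '28'
  x: -1.0
  y: 2.309401077
  features: []
- label: '30'
  x: 0.0
  y: 2.309401077
  features: []
- label: '32'
  x: 1.0
  y: 2.309401077
  features: []
- label: '34'
  x: 2.0
  y: 2.309401077
  features: []
- label: eJ1
  x: 3.0
  y: 2.309401077
  features: []
- label: 36'
  x: -2.0
  y: 2.886751346
  features:
  - on_left_end
- label: '37'
  x: -1.0
  y: 2.886751346
  features: []
- label: '39'
  x: 0.0
  y: 2.886751346
  features: []
- label: '41'
  x: 1.0
  y: 2.886751346
  features: []
- label: '43'
  x: 2.0
  y: 2.886751346
  features: []
- label: eO2
  x: 3.0
  y: 2.886751346
  features: []
- label: eR2
  x: -2.5
  y: 3.175426481
  features:
  - on_left_end
- label: '36'
  x: -1.5
  y: 3.175426481
  features: []
- label: '38'
  x: -0.5
  y: 3.175426481
  features: []
- label: '40'
  x: 0.5
  y: 3.175426481
  features: []
- label: '42'
  x: 1.5
  y: 3.175426481
  features: []
- label: eO1
  x: 2.5
  y: 3.175426481
  features: []
- label: eR1
  x: -2.5
  y: 3.75277675
  features:
  - on_left_end
- label: '44'
  x: -1.5
  y: 3.75277675
  features: []
- label: '46'
  x: -0.5
  y: 3.75277675
  features: []
- label: '48'
  x: 0.5
  y: 3.75277675
  features: []
- label: '50'
  x: 1.5
  y: 3.75277675
  features: []
- label: eP2
  x: 2.5
  y: 3.75277675
  features: []
- label: 44'
  x: -2.0
  y: 4.041451884
  features:
  - on_left_end
- label: '45'
  x: -1.0
  y: 4.041451884
  features: []
- label: '47'
  x: 0.0
  y: 4.041451884
  features: []
- label: '49'
  x: 1.0
  y: 4.041451884
  features: []
- label: eP1
  x: 2.0
  y: 4.041451884
  features: []
- label: 54'
  x: -2.0
  y: 4.618802154
  features:
  - entrance_anchor
  - on_left_end
- label: '51'
  x: -1.0
  y: 4.618802154
  features: []
- label: '53'
  x: 0.0
  y: 4.618802154
  features: []
- label: 49'
  x: 1.0
  y: 4.618802154
  features:
  - entrance_anchor
- label: eU2
  x: 2.0
  y: 4.618802154
  features: []
- label: 51'
  x: -1.5
  y: 4.907477288
  features: []
- label: '52'
  x: -0.5
  y: 4.907477288
  features: []
- label: '54'
  x: 0.5
  y: 4.907477288
  features: []
- label: eU1
  x: 1.5
  y: 4.907477288
  features: []
rings:
  A:
  - '9'
  - '10'
  - '11'
  - '3'
  - '2'
  - '1'
  B:
  - '11'
  - '12'
  - '13'
  - '5'
  - '4'
  - '3'
  C:
  - '13'
  - '14'
  - '15'
  - '7'
  - '6'
  - '5'
  D:
  - '20'
  - '21'
  - '22'
  - '12'
  - '11'
  - '10'
  E:
  - '18'
  - '19'
  - '20'
  - '10'
  - '9'
  - '8'
  F:
  - '27'
  - '28'
  - '29'
  - '19'
  - '18'
  - '17'
  G:
  - '29'
  - '30'
  - '31'
  - '21'
  - '20'
  - '19'
  H:
  - '22'
  - '23'
  - '24'
  - '14'
  - '13'
  - '12'
  I:
  - '24'
  - '25'
  - '26'
  - '16'
  - '15'
  - '14'
  J:
  - '33'
  - '34'
  - '35'
  - '25'
  - '24'
  - '23'
  K:
  - '31'
  - '32'
  - '33'
  - '23'
  - '22'
  - '21'
  L:
  - '37'
  - '38'
  - '39'
  - '30'
  - '29'
  - '28'
  M:
  - 36'
  - '36'
  - '37'
  - '28'
  - '27'
  - 27'
  N:
  - '39'
  - '40'
  - '41'
  - '32'
  - '31'
  - '30'
  O:
  - '41'
  - '42'
  - '43'
  - '34'
  - '33'
  - '32'
  P:
  - '48'
  - '49'
  - '50'
  - '42'
  - '41'
  - '40'
  Q:
  - '46'
  - '47'
  - '48'
  - '40'
  - '39'
  - '38'
  R:
  - '44'
  - '45'
  - '46'
  - '38'
  - '37'
  - '36'
  S:
  - 54'
  - 51'
  - '51'
  - '45'
  - '44'
  - 44'
  T:
  - '51'
  - '52'
  - '53'
  - '47'
  - '46'
  - '45'
  U:
  - '53'
  - '54'
  - 49'
  - '49'
  - '48'
  - '47'
  eB:
  - '15'
  - '16'
  - eB1
  - eB2
  - eB3
  - '7'
  eC:
  - '26'
  - eC1
  - eC2
  - eC3
  - eB1
  - '16'
  eE:
  - eE1
  - '17'
  - '18'
  - '8'
  - eE2
  - 11'
  eJ:
  - '35'
  - eJ1
  - eJ2
  - eC1
  - '26'
  - '25'
  eL:
  - eL1
  - 27'
  - '27'
  - '17'
  - eE1
  - eL2
  eO:
  - '43'
  - eO1
  - eO2
  - eJ1
  - '35'
  - '34'
  eP:
  - '50'
  - eP1
  - eP2
  - eO1
  - '43'
  - '42'
  eR:
  - eR1
  - 44'
  - '44'
  - '36'
  - 36'
  - eR2
  eU:
  - 49'
  - eU1
  - eU2
  - eP1
  - '50'
  - '49'
site_of_oxidation:
- '2'
- '3'
- '4'
shelf:
  edge:
  - 11'
  - '8'
  - '10'
  forbidden:
  - eE2
left_end:
- 11'
- eE1
- eL2
- eL1
- 27'
- 36'
- eR2
- eR1
- 44'
- 54'
entrance:
- 49'
- 54'
trigger_path:
- eB
- C
- B
trigger_pillar:
- 0.5
- 0.5
- 3.0
pillar_rings:
- K
- J
- O
heme_access: rear
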