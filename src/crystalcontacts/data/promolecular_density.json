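{
 "_provenance": "Slater-screened shell model (synthetic)",
 "H": [
  [
   0.3183098861837907,
   0.5
  ]
 ],
 "C": [
  [
   117.97537212090147,
   0.0877
  ],
  [
   5.463081039505146,
   0.3077
  ]
 ],
 "N": [
  [
   191.67861098074908,
   0.0746
  ],
  [
   11.802556336694058,
   0.2564
  ]
 ],
 "O": [
  [
   291.1092769503924,
   0.0649
  ],
  [
   22.481657460046872,
   0.2198
  ]
 ],
 "F": [
  [
   418.58783421884203,
   0.0575
  ],
  [
   39.16700176917734,
   0.1923
  ]
 ],
 "S": [
  [
   2474.621466849332,
   0.0318
  ],
  [
   546.7524035017187,
   0.0835
  ],
  [
   11.454235341982889,
   0.2752
  ]
 ],
 "Cl": [
  [
   2918.03602477042,
   0.0301
  ],
  [
   675.9449633352141,
   0.0778
  ],
  [
   18.731932929908453,
   0.2459
  ]
 ],
 "Br": [
  [
   25464.79089470325,
   0.025
  ],
  [
   1398.822742018611,
   0.08
  ],
  [
   19.315077659860023,
   0.2434
  ]
 ],
 "I": [
  [
   42963.75744841144,
   0.021
  ],
  [
   1419.0769960182713,
   0.09
  ],
  [
   15.975359131222893,
   0.2593
  ]
 ]
}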