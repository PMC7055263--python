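{
 "action_label": "Stir",
 "channels": [
  "TNT",
  "SSR",
  "DSR"
 ],
 "columns": [
  [
   "U",
   "U",
   "U",
   "N",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U",
   "O",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U",
   "Q",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U"
  ],
  [
   "U",
   "U",
   "U",
   "N",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U",
   "Ab",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U",
   "GC",
   "U",
   "U",
   "U",
   "U",
   "U",
   "U"
  ],
  [
   "T",
   "U",
   "U",
   "N",
   "U",
   "U",
   "T",
   "U",
   "U",
   "U",
   "ArT",
   "U",
   "U",
   "Ab",
   "U",
   "U",
   "To",
   "U",
   "U",
   "U",
   "HT",
   "U",
   "U",
   "S",
   "U",
   "U",
   "S",
   "U",
   "U",
   "U"
  ],
  [
   "T",
   "U",
   "U",
   "N",
   "U",
   "U",
   "N",
   "U",
   "U",
   "U",
   "ArT",
   "U",
   "U",
   "Ab",
   "U",
   "U",
   "Ab",
   "U",
   "U",
   "U",
   "MT",
   "U",
   "U",
   "MA",
   "U",
   "U",
   "MA",
   "U",
   "U",
   "U"
  ],
  [
   "T",
   "N",
   "U",
   "N",
   "T",
   "U",
   "N",
   "U",
   "T",
   "U",
   "ArT",
   "Ab",
   "U",
   "Ab",
   "In",
   "U",
   "Ab",
   "U",
   "To",
   "U",
   "MT",
   "S",
   "U",
   "FMT",
   "S",
   "U",
   "FMT",
   "U",
   "S",
   "U"
  ],
  [
   "T",
   "N",
   "U",
   "N",
   "N",
   "U",
   "N",
   "U",
   "T",
   "U",
   "ArT",
   "Ab",
   "U",
   "Ab",
   "Ab",
   "U",
   "Ab",
   "U",
   "To",
   "U",
   "MT",
   "GC",
   "U",
   "GC",
   "GC",
   "U",
   "GC",
   "U",
   "S",
   "U"
  ],
  [
   "T",
   "N",
   "U",
   "N",
   "N",
   "U",
   "N",
   "U",
   "T",
   "U",
   "ArT",
   "Ab",
   "U",
   "Ab",
   "Ab",
   "U",
   "Ab",
   "U",
   "To",
   "U",
   "MT",
   "S",
   "U",
   "GC",
   "MA",
   "U",
   "GC",
   "U",
   "S",
   "U"
  ],
  [
   "T",
   "N",
   "U",
   "N",
   "N",
   "U",
   "N",
   "U",
   "T",
   "U",
   "ArT",
   "Ab",
   "U",
   "Ab",
   "R",
   "U",
   "Ab",
   "U",
   "To",
   "U",
   "MT",
   "MA",
   "U",
   "GC",
   "MA",
   "U",
   "GC",
   "U",
   "S",
   "U"
  ],
  [
   "T",
   "N",
   "U",
   "N",
   "N",
   "U",
   "N",
   "U",
   "T",
   "U",
   "ArT",
   "R",
   "U",
   "Ab",
   "R",
   "U",
   "Ab",
   "U",
   "To",
   "U",
   "MT",
   "MA",
   "U",
   "GC",
   "MA",
   "U",
   "GC",
   "U",
   "S",
   "U"
  ],
  [
   "T",
   "N",
   "U",
   "N",
   "N",
   "U",
   "T",
   "U",
   "T",
   "U",
   "ArT",
   "R",
   "U",
   "Ab",
   "R",
   "U",
   "To",
   "U",
   "To",
   "U",
   "HT",
   "HT",
   "U",
   "S",
   "HT",
   "U",
   "S",
   "U",
   "S",
   "U"
  ],
  [
   "N",
   "N",
   "U",
   "N",
   "N",
   "U",
   "T",
   "U",
   "T",
   "U",
   "AR",
   "R",
   "U",
   "Ab",
   "R",
   "U",
   "To",
   "U",
   "To",
   "U",
   "MA",
   "MA",
   "U",
   "MA",
   "HT",
   "U",
   "S",
   "U",
   "S",
   "U"
  ],
  [
   "N",
   "N",
   "U",
   "N",
   "N",
   "U",
   "T",
   "U",
   "T",
   "U",
   "AR",
   "Ab",
   "U",
   "Ab",
   "R",
   "U",
   "To",
   "U",
   "To",
   "U",
   "MA",
   "MA",
   "U",
   "MA",
   "HT",
   "U",
   "S",
   "U",
   "S",
   "U"
  ],
  [
   "N",
   "N",
   "U",
   "N",
   "N",
   "U",
   "T",
   "U",
   "T",
   "U",
   "AR",
   "O",
   "U",
   "Ab",
   "R",
   "U",
   "To",
   "U",
   "To",
   "U",
   "MA",
   "Q",
   "U",
   "MA",
   "HT",
   "U",
   "S",
   "U",
   "S",
   "U"
  ],
  [
   "N",
   "N",
   "U",
   "N",
   "N",
   "U",
   "T",
   "U",
   "T",
   "U",
   "O",
   "O",
   "U",
   "O",
   "R",
   "U",
   "To",
   "U",
   "To",
   "U",
   "Q",
   "Q",
   "U",
   "Q",
   "HT",
   "U",
   "S",
   "U",
   "S",
   "U"
  ]
 ],
 "meta": {
  "action_label": "Stir",
  "n_event_columns": 13,
  "provenance": "synthetic reconstruction: extracted from the package's scripted block-world trajectory at canonical (variant-free) parameters; not recorded human data"
 },
 "pairs": [
  "H-O1",
  "H-O2",
  "H-O3",
  "H-G",
  "O1-O2",
  "O1-O3",
  "O1-G",
  "O2-O3",
  "O2-G",
  "O3-G"
 ],
 "timestamps": [
  0.0,
  0.925,
  2.5,
  3.0,
  4.2,
  7.3,
  7.675,
  7.875,
  8.075,
  8.675,
  9.2,
  10.4,
  12.475,
  12.725
 ]
}
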