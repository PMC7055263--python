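{
 "action_label": "Cut",
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
   "To",
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
   "N",
   "N",
   "T",
   "N",
   "N",
   "N",
   "T",
   "T",
   "ArT",
   "Ab",
   "Ab",
   "Ab",
   "To",
   "R",
   "Ab",
   "R",
   "To",
   "To",
   "MT",
   "GC",
   "MA",
   "GC",
   "GC",
   "MA",
   "GC",
   "MA",
   "S",
   "FMT"
  ],
  [
   "T",
   "N",
   "N",
   "N",
   "N",
   "N",
   "N",
   "N",
   "T",
   "T",
   "ArT",
   "Ab",
   "Ab",
   "Ab",
   "Ab",
   "R",
   "Ab",
   "R",
   "To",
   "To",
   "MT",
   "MA",
   "MA",
   "MA",
   "MA",
   "MA",
   "MA",
   "HT",
   "S",
   "S"
  ],
  [
   "T",
   "N",
   "N",
   "N",
   "N",
   "N",
   "N",
   "N",
   "T",
   "T",
   "ArT",
   "Ab",
   "Ab",
   "Ab",
   "Ab",
   "R",
   "Ab",
   "R",
   "To",
   "To",
   "MT",
   "GC",
   "MA",
   "GC",
   "GC",
   "MA",
   "GC",
   "HT",
   "S",
   "S"
  ],
  [
   "T",
   "N",
   "N",
   "N",
   "N",
   "N",
   "N",
   "N",
   "T",
   "T",
   "ArT",
   "Ab",
   "R",
   "Ab",
   "Ab",
   "R",
   "Ab",
   "R",
   "To",
   "To",
   "MT",
   "S",
   "MA",
   "GC",
   "MA",
   "MA",
   "GC",
   "HT",
   "S",
   "S"
  ],
  [
   "T",
   "N",
   "N",
   "N",
   "N",
   "N",
   "N",
   "N",
   "T",
   "T",
   "ArT",
   "Ab",
   "R",
   "Ab",
   "R",
   "R",
   "Ab",
   "R",
   "To",
   "To",
   "MT",
   "MA",
   "MA",
   "GC",
   "MA",
   "MA",
   "GC",
   "HT",
   "S",
   "S"
  ],
  [
   "T",
   "N",
   "N",
   "N",
   "N",
   "N",
   "N",
   "N",
   "T",
   "T",
   "ArT",
   "R",
   "R",
   "Ab",
   "R",
   "R",
   "Ab",
   "R",
   "To",
   "To",
   "MT",
   "MA",
   "MA",
   "GC",
   "MA",
   "MA",
   "GC",
   "HT",
   "S",
   "S"
  ],
  [
   "T",
   "N",
   "N",
   "N",
   "N",
   "N",
   "T",
   "N",
   "T",
   "T",
   "ArT",
   "R",
   "R",
   "Ab",
   "R",
   "R",
   "To",
   "R",
   "To",
   "To",
   "HT",
   "HT",
   "HT",
   "S",
   "HT",
   "HT",
   "S",
   "HT",
   "S",
   "S"
  ],
  [
   "N",
   "N",
   "N",
   "N",
   "N",
   "N",
   "T",
   "N",
   "T",
   "T",
   "AR",
   "R",
   "R",
   "Ab",
   "R",
   "R",
   "To",
   "R",
   "To",
   "To",
   "MA",
   "MA",
   "MA",
   "MA",
   "HT",
   "HT",
   "S",
   "HT",
   "S",
   "S"
  ],
  [
   "N",
   "N",
   "N",
   "N",
   "N",
   "N",
   "T",
   "N",
   "T",
   "T",
   "AR",
   "Ab",
   "R",
   "Ab",
   "R",
   "R",
   "To",
   "R",
   "To",
   "To",
   "MA",
   "MA",
   "MA",
   "MA",
   "HT",
   "HT",
   "S",
   "HT",
   "S",
   "S"
  ],
  [
   "N",
   "N",
   "N",
   "N",
   "N",
   "N",
   "T",
   "N",
   "T",
   "T",
   "AR",
   "Ab",
   "Ab",
   "Ab",
   "R",
   "R",
   "To",
   "R",
   "To",
   "To",
   "MA",
   "MA",
   "MA",
   "MA",
   "HT",
   "HT",
   "S",
   "HT",
   "S",
   "S"
  ],
  [
   "N",
   "N",
   "N",
   "N",
   "N",
   "N",
   "T",
   "N",
   "T",
   "T",
   "AR",
   "Ab",
   "O",
   "Ab",
   "R",
   "R",
   "To",
   "R",
   "To",
   "To",
   "MA",
   "MA",
   "Q",
   "MA",
   "HT",
   "HT",
   "S",
   "HT",
   "S",
   "S"
  ],
  [
   "N",
   "N",
   "N",
   "N",
   "N",
   "N",
   "T",
   "N",
   "T",
   "T",
   "AR",
   "O",
   "O",
   "Ab",
   "R",
   "R",
   "To",
   "R",
   "To",
   "To",
   "MA",
   "Q",
   "Q",
   "MA",
   "HT",
   "HT",
   "S",
   "HT",
   "S",
   "S"
  ],
  [
   "N",
   "N",
   "N",
   "N",
   "N",
   "N",
   "T",
   "N",
   "T",
   "T",
   "O",
   "O",
   "O",
   "O",
   "R",
   "R",
   "To",
   "R",
   "To",
   "To",
   "Q",
   "Q",
   "Q",
   "Q",
   "HT",
   "HT",
   "S",
   "HT",
   "S",
   "S"
  ]
 ],
 "meta": {
  "action_label": "Cut",
  "n_event_columns": 17,
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
  4.825,
  5.2,
  5.375,
  5.625,
  5.8,
  6.05,
  6.575,
  7.1,
  7.725,
  8.1,
  8.675,
  8.875,
  9.075
 ]
}
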