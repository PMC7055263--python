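{
 "action_label": "Chop",
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
   "Ab",
   "Ab",
   "R",
   "To",
   "To",
   "HT",
   "HT",
   "MA",
   "S",
   "HT",
   "MA",
   "S",
   "MA",
   "S",
   "FMT"
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
   "HT",
   "HT",
   "MA",
   "S",
   "HT",
   "MA",
   "S",
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
   "Ab",
   "Ab",
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
  "action_label": "Chop",
  "n_event_columns": 19,
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
  4.6,
  5.1,
  5.275,
  5.5,
  6.0,
  6.225,
  6.4,
  6.65,
  7.175,
  7.7,
  8.325,
  8.7,
  9.275,
  9.475,
  9.675
 ]
}
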