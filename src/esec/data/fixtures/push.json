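{
 "action_label": "Push",
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
   "FMT",
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
   "L",
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
   "T",
   "U",
   "U",
   "U",
   "L",
   "U",
   "U",
   "Ab",
   "U",
   "U",
   "To",
   "U",
   "U",
   "U",
   "MT",
   "U",
   "U",
   "FMT",
   "U",
   "U",
   "FMT",
   "U",
   "U",
   "U"
  ],
  [
   "N",
   "U",
   "U",
   "N",
   "U",
   "U",
   "T",
   "U",
   "U",
   "U",
   "L",
   "U",
   "U",
   "Ab",
   "U",
   "U",
   "To",
   "U",
   "U",
   "U",
   "MA",
   "U",
   "U",
   "MA",
   "U",
   "U",
   "S",
   "U",
   "U",
   "U"
  ],
  [
   "N",
   "U",
   "U",
   "N",
   "U",
   "U",
   "T",
   "U",
   "U",
   "U",
   "O",
   "U",
   "U",
   "Ab",
   "U",
   "U",
   "To",
   "U",
   "U",
   "U",
   "Q",
   "U",
   "U",
   "MA",
   "U",
   "U",
   "S",
   "U",
   "U",
   "U"
  ],
  [
   "N",
   "U",
   "U",
   "N",
   "U",
   "U",
   "T",
   "U",
   "U",
   "U",
   "O",
   "U",
   "U",
   "O",
   "U",
   "U",
   "To",
   "U",
   "U",
   "U",
   "Q",
   "U",
   "U",
   "Q",
   "U",
   "U",
   "S",
   "U",
   "U",
   "U"
  ]
 ],
 "meta": {
  "action_label": "Push",
  "n_event_columns": 7,
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
  1.7,
  5.0,
  5.8,
  6.1,
  7.3,
  10.275,
  12.225
 ]
}
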