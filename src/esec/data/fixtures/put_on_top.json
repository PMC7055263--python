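{
 "action_label": "Put on top",
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
   "To",
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
   "To",
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
   "To",
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
   "N",
   "N",
   "U",
   "N",
   "T",
   "U",
   "N",
   "U",
   "T",
   "U",
   "Ab",
   "Ab",
   "U",
   "Ab",
   "To",
   "U",
   "Ab",
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
   "T",
   "U",
   "N",
   "U",
   "T",
   "U",
   "Ab",
   "O",
   "U",
   "O",
   "To",
   "U",
   "Ab",
   "U",
   "To",
   "U",
   "MA",
   "Q",
   "U",
   "Q",
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
   "T",
   "U",
   "N",
   "U",
   "T",
   "U",
   "O",
   "O",
   "U",
   "O",
   "To",
   "U",
   "Ab",
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
  "action_label": "Put on top",
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
  2.175,
  6.0,
  6.5,
  8.0,
  8.7,
  11.575,
  11.95
 ]
}
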