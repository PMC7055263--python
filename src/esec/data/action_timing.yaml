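# Average per-action timings from human VR demonstrations of the five
# chain actions, seconds: [mean, std].
#   duration -- total action time
#   esec     -- prediction moment of the full relational encoding
#   sec      -- prediction moment of the touch-only encoding
"Take down":
  duration: [11.7, 2.9]
  esec: [3.3, 0.7]
  sec: [3.3, 0.7]
"Put on top":
  duration: [12.0, 2.1]
  esec: [8.0, 1.9]
  sec: [9.2, 1.7]
"Shake":
  duration: [12.5, 2.1]
  esec: [6.5, 1.2]
  sec: [10.8, 1.7]
"Push":
  duration: [12.7, 1.9]
  esec: [5.0, 1.1]
  sec: [10.0, 1.6]
"Hide":
  duration: [13.8, 2.5]
  esec: [8.3, 1.6]
  sec: [10.3, 1.5]
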