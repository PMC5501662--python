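{
 "units": "um",
 "bin_edges": [
  1.0,
  1.25,
  1.5,
  1.75,
  2.0,
  2.25,
  2.5,
  2.75,
  3.0,
  3.25,
  3.5,
  3.75,
  4.0,
  4.25,
  4.5,
  4.75,
  5.0,
  5.25,
  5.5,
  5.75,
  6.0,
  6.25,
  6.5,
  6.75,
  7.0,
  7.25,
  7.5,
  7.75,
  8.0,
  8.25,
  8.5,
  8.75,
  9.0,
  9.25,
  9.5,
  9.75,
  10.0
 ],
 "mass": [
  0.047012647839966185,
  0.06436921737303604,
  0.07564808955032883,
  0.08075063553019253,
  0.08088108172644079,
  0.07754773812620377,
  0.07209544924788776,
  0.06555745073289711,
  0.05865694902146276,
  0.051862958570004995,
  0.045455582515915686,
  0.03958321704881415,
  0.03430699677768149,
  0.029633067467837768,
  0.02553497431459502,
  0.021968641046722515,
  0.018882057476043816,
  0.016221312791504214,
  0.013934171679444506,
  0.011972037898476057,
  0.010290886358620018,
  0.00885155546767745,
  0.0076196591653880045,
  0.006565287313802535,
  0.005662601833328667,
  0.004889395157406101,
  0.004226650756720156,
  0.003658128118896279,
  0.0031699835288029575,
  0.0027504311401119613,
  0.0023894447153786115,
  0.0020784980704718153,
  0.0018103410448486814,
  0.0015788073062952795,
  0.001378650209049939,
  0.0012054030777455236
 ],
 "description": "fibroblast-like mitochondrial length table (truncated log-normal surrogate, mode ~2 um)"
}
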