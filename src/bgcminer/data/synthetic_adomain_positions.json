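{
 "comment": "synthetic stand-in signature positions (0-based indices into the reference)",
 "positions10": [
  176,
  219,
  248,
  267,
  340,
  359,
  364,
  385,
  389,
  390
 ],
 "positions34": [
  163,
  165,
  168,
  176,
  186,
  216,
  219,
  221,
  239,
  248,
  249,
  263,
  267,
  288,
  292,
  300,
  330,
  340,
  345,
  350,
  359,
  364,
  367,
  370,
  375,
  385,
  389,
  390,
  405,
  407,
  408,
  409,
  413,
  419
 ]
}
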