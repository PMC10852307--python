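# Default 2030 land-demand scenario specifications for an oasis city.
# Areas in hm2; objective coefficients in 10^4 yuan per hm2.
# Classes in canonical order: APL, IPL, ULL, RLL, FEL, GEL, WEL, OEL.
total_area: 732360.78
classes: [APL, IPL, ULL, RLL, FEL, GEL, WEL, OEL]
bounds:
  APL: [135559.17, 144917.10]
  IPL: [2054.16, 3319.02]
  ULL: [4312.80, 4424.58]
  RLL: [6737.22, 9719.19]
  FEL: [20140.53, 22562.69]
  GEL: [353841.57, 357380.01]
  WEL: [48977.01, 49388.31]
  OEL: [0.0, 151034.49]
population:
  # people per hm2 on each class; zero where no resident population.
  coefficients: {APL: 0.006, IPL: 0.0, ULL: 40.0, RLL: 1.3, FEL: 0.0015, GEL: 0.003, WEL: 0.0, OEL: 0.0}
  cap: 320000.0
objectives:
  economic:   # F1: maximize economic benefit
    APL: 2.53
    IPL: 278.26
    ULL: 278.26
    RLL: 278.26
    FEL: 0.93
    GEL: 0.51
    WEL: 0.007
    OEL: 0.0
  ecological:  # F2: maximize ecological benefit
    APL: 0.9
    IPL: 0.0
    ULL: 0.0
    RLL: 0.0
    FEL: 3.93
    GEL: 2.63
    WEL: 19.95
    OEL: 0.16
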