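{
 "v1": 4.58,
 "v1L": 3.0,
 "v2A": 1.27,
 "v2L": 5.0,
 "v3": 1.0,
 "v4": 1.47,
 "k1L": 0.53,
 "k1D": 0.21,
 "k2": 0.35,
 "k3": 0.4989,
 "k4": 0.57,
 "p1": 0.76,
 "p1L": 0.42,
 "p2": 1.01,
 "p3": 0.64,
 "p4": 1.01,
 "d1": 0.68,
 "d2D": 0.5,
 "d2L": 0.29,
 "d3D": 0.48,
 "d3L": 0.3831,
 "d4D": 1.21,
 "d4L": 0.38,
 "K0": 1.0518,
 "K1": 0.1644,
 "K2": 1.2058,
 "K4": 0.3182,
 "K5": 1.336,
 "K5b": 1.791,
 "K6": 0.5409,
 "K7": 3.0545,
 "K8": 0.36,
 "K9": 1.9,
 "K10": 1.9,
 "q": 0.3
}
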