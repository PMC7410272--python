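# Published time-zero bone-implant interface failure thresholds (cadaveric,
# cementless press-fit transhumeral stems).  Moments in N.m, forces in N.
# Ranges aggregate test conditions (amputation level x stabilizing screws);
# narrower screw/level splits are listed where the source reports them.
# The drew_taylor with-screws torsional ultimate entry uses the upper end of
# the printed aggregate range (per-level with-screw means are not published).
version: 1
envelopes:
  - modality: bending
    level: unspecified
    screws: unspecified
    yield_lo: 1.7
    yield_hi: 2.3
    ultimate_lo: 70.3
    ultimate_hi: 119.4
    source: drew_taylor
  - modality: torsion
    level: unspecified
    screws: unspecified
    yield_lo: 4.5
    yield_hi: 10.2
    ultimate_lo: 6.0
    ultimate_hi: 42.2
    source: drew_taylor
  - modality: axial
    level: unspecified
    screws: unspecified
    yield_lo: 784.2
    yield_hi: 1818.1
    ultimate_lo: 1325.1
    ultimate_hi: 5120.3
    source: drew_taylor
  - modality: torsion
    level: proximal
    screws: without
    yield_lo: 4.5
    yield_hi: 4.5
    ultimate_lo: 6.0
    ultimate_hi: 6.0
    source: drew_taylor
  - modality: torsion
    level: unspecified
    screws: without
    yield_lo: 4.5
    yield_hi: 4.5
    ultimate_lo: 6.0
    ultimate_hi: 12.7
    source: drew_taylor
  - modality: torsion
    level: unspecified
    screws: with
    ultimate_lo: 42.2
    ultimate_hi: 42.2
    source: drew_taylor
  - modality: bending
    level: unspecified
    screws: unspecified
    ultimate_lo: 36.7
    ultimate_hi: 36.7
    ultimate_sd: 11.0
    source: welke
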