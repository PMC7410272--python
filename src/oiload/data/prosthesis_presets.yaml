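# Prosthetic arm component metrics for the four modelled categories.
# Lengths in metres, masses in kg.  Forearm mass includes the integrated
# elbow components.  COM offsets are fractions of segment length from the
# proximal end; manufacturer values are not published, so they default to
# proximal-of-center (0.45) and are configurable here.
presets:
  body_powered:
    elbow_width: 0.0635
    forearm_mass: 0.555
    wrist_width: 0.0381
    hand_mass: 0.027
    hand_length: 0.1016
    forearm_com_offset: 0.45
    hand_com_offset: 0.45
  myoelectric_hook:
    elbow_width: 0.0762
    forearm_mass: 1.013
    wrist_width: 0.0540
    hand_mass: 0.416
    hand_length: 0.1524
    forearm_com_offset: 0.45
    hand_com_offset: 0.45
  myoelectric_hand:
    elbow_width: 0.0825
    forearm_mass: 1.040
    wrist_width: 0.0635
    hand_mass: 0.500
    hand_length: 0.2159
    forearm_com_offset: 0.45
    hand_com_offset: 0.45
  advanced:
    elbow_width: 0.0773
    forearm_mass: 1.875
    wrist_width: 0.0635
    hand_mass: 1.525
    hand_length: 0.1950
    forearm_com_offset: 0.45
    hand_com_offset: 0.45
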