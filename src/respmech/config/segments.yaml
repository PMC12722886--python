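# Default 14-segment proportional body model.
# Mass fractions and COM locations (fraction of the proximal->distal axis)
# follow standard adult male anthropometric tables; edit to match a
# subject-specific model.  Fractions must sum to 1.
segments:
  head_neck:  {proximal: HEADT, distal: C7,   mass_fraction: 0.0694, com_fraction: 0.5002}
  trunk:      {proximal: C7,    distal: SACR, mass_fraction: 0.4346, com_fraction: 0.5138}
  upper_arm_L: {proximal: LSHO, distal: LELB, mass_fraction: 0.0271, com_fraction: 0.5772}
  upper_arm_R: {proximal: RSHO, distal: RELB, mass_fraction: 0.0271, com_fraction: 0.5772}
  forearm_L:  {proximal: LELB,  distal: LWRI, mass_fraction: 0.0162, com_fraction: 0.4574}
  forearm_R:  {proximal: RELB,  distal: RWRI, mass_fraction: 0.0162, com_fraction: 0.4574}
  hand_L:     {proximal: LWRI,  distal: LFIN, mass_fraction: 0.0061, com_fraction: 0.7900}
  hand_R:     {proximal: RWRI,  distal: RFIN, mass_fraction: 0.0061, com_fraction: 0.7900}
  thigh_L:    {proximal: LHIP,  distal: LKNE, mass_fraction: 0.1416, com_fraction: 0.4095}
  thigh_R:    {proximal: RHIP,  distal: RKNE, mass_fraction: 0.1416, com_fraction: 0.4095}
  shank_L:    {proximal: LKNE,  distal: LANK, mass_fraction: 0.0433, com_fraction: 0.4459}
  shank_R:    {proximal: RKNE,  distal: RANK, mass_fraction: 0.0433, com_fraction: 0.4459}
  foot_L:     {proximal: LANK,  distal: LTOE, mass_fraction: 0.0137, com_fraction: 0.4415}
  foot_R:     {proximal: RANK,  distal: RTOE, mass_fraction: 0.0137, com_fraction: 0.4415}
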