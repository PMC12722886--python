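# Default 32-marker chest-wall grid: 4 rings (cranial -> caudal: sternal
# notch, xiphoid, 10th rib, umbilical levels) x 8 circumferential columns
# (counterclockwise viewed from above, starting at the sternal midline).
# compartment_rows split the rings into upper-thoracic / lower-thoracic /
# abdominal bands at the xiphoid (row 1) and 10th-rib (row 2) rings.
rows: 4
cols: 8
compartment_rows: [1, 2]
cells:
  CW_0_0: [0, 0]
  CW_0_1: [0, 1]
  CW_0_2: [0, 2]
  CW_0_3: [0, 3]
  CW_0_4: [0, 4]
  CW_0_5: [0, 5]
  CW_0_6: [0, 6]
  CW_0_7: [0, 7]
  CW_1_0: [1, 0]
  CW_1_1: [1, 1]
  CW_1_2: [1, 2]
  CW_1_3: [1, 3]
  CW_1_4: [1, 4]
  CW_1_5: [1, 5]
  CW_1_6: [1, 6]
  CW_1_7: [1, 7]
  CW_2_0: [2, 0]
  CW_2_1: [2, 1]
  CW_2_2: [2, 2]
  CW_2_3: [2, 3]
  CW_2_4: [2, 4]
  CW_2_5: [2, 5]
  CW_2_6: [2, 6]
  CW_2_7: [2, 7]
  CW_3_0: [3, 0]
  CW_3_1: [3, 1]
  CW_3_2: [3, 2]
  CW_3_3: [3, 3]
  CW_3_4: [3, 4]
  CW_3_5: [3, 5]
  CW_3_6: [3, 6]
  CW_3_7: [3, 7]
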