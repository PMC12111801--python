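# BOILED-Egg best-fit ellipse parameters in (TPSA [A^2], WLOGP) space.
# gi  = "white" region: high passive gastrointestinal absorption
# bbb = "yolk" region: passive blood-brain-barrier permeation
# rotation is in radians, anticlockwise about the center.
gi:
  center_tpsa: 71.051
  center_wlogp: 2.292
  semi_axis_tpsa: 71.0405
  semi_axis_wlogp: 4.370
  rotation: -0.0180000
bbb:
  center_tpsa: 38.117
  center_wlogp: 3.177
  semi_axis_tpsa: 41.0305
  semi_axis_wlogp: 2.7785
  rotation: -0.0046542
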