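# Synthetic cytokinesis centrosome-position presets (µm, embryo-centered
# coordinates, major axis = x, posterior at +x).
#
# The measured per-condition coordinates are figure-derived and not printed
# in text form, so these are editable placeholders at physiologically
# plausible spindle geometries; replace with measured values for
# quantitative comparisons.  All conditions use sigma_c = 0.7 µm and
# C0/D = 1.
wild_type:
  centers: [[7.0, 0.0], [-7.0, 0.0]]
par-2_RNAi:
  centers: [[6.0, 0.0], [-6.0, 0.0]]
dhc-1_RNAi:   # posterior-displaced spindle
  centers: [[14.0, 0.0], [1.0, 0.0]]
zyg-9_b244:   # short spindle, posterior
  centers: [[19.0, 0.0], [11.0, 0.0]]
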