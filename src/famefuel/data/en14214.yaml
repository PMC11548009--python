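# European biodiesel quality standard (FAME for diesel engines) —
# the composition-derived subset this pipeline can evaluate.
name: EN14214
criteria:
  - property: iv
    bound: max
    threshold: 120
    units: g I2/100 g
  - property: cn
    bound: min
    threshold: 51
    units: ""
  - property: os_hours
    bound: min
    threshold: 6
    units: h
  # CFPP limits are national climate-class choices spanning roughly
  # -20..+5 degC; informational unless a user sets a concrete limit.
  - property: cfpp
    bound: informational
    threshold: [-20, 5]
    units: degC
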