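# US biodiesel blend-stock standard (2002 edition) — the
# composition-derived subset this pipeline can evaluate. SV/IV/DU carry
# no limit in this standard and are therefore absent, not zero.
name: ASTM D6751-02
criteria:
  - property: cn
    bound: min
    threshold: 47
    units: ""
  - property: os_hours
    bound: min
    threshold: 3
    units: h
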