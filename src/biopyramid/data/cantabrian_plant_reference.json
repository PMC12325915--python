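{
  "total_agb_tonnes": 9367452.0,
  "available_tonnes": 1170932.0,
  "study_area_km2": 1125.0
}
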