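{
  "type": "Feature",
  "properties": {"name": "synthetic square range (planar km coordinates)"},
  "geometry": {
    "type": "Polygon",
    "coordinates": [[[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0], [0.0, 0.0]]]
  }
}
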