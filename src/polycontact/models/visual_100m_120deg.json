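{
 "comment": "Binocular visual-field triangle: apex at the neck-collar location, 100-m height along the forward direction (+y in the template frame), 120-degree apex angle, 30-degree base angles. Base half-width = 100 * tan(60 deg).",
 "reference_point": [0.0, 0.0],
 "forward_direction_deg": 90.0,
 "parts": {
  "visual": [[0.0, 0.0], [173.20508075688772, 100.0], [-173.20508075688772, 100.0]]
 }
}
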