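{
 "comment": "Three-part calf body template (head 0.333 m x 0.333 m, anterior and posterior bodies 1 m x 1 m), forward along +x. The tag sits on the left ear (facing forward, left = +y), near the rear of the head. Part placement along the body axis is an approximation documented in docs/methods.md; layout-sensitive analyses should supply their own model file.",
 "reference_point": [0.0, 0.25],
 "forward_direction_deg": 0.0,
 "parts": {
  "head": [[0.0, -0.1665], [0.333, -0.1665], [0.333, 0.1665], [0.0, 0.1665]],
  "anterior": [[-1.0, -0.5], [0.0, -0.5], [0.0, 0.5], [-1.0, 0.5]],
  "posterior": [[-2.0, -0.5], [-1.0, -0.5], [-1.0, 0.5], [-2.0, 0.5]]
 }
}
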