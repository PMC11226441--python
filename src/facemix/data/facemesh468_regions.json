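{
  "n_landmarks": 468,
  "convention": "MediaPipe FaceMesh contour indices: lips and eye contours per the published topology; head_rigid = nose bridge plus face-oval anchor points commonly used for rigid head-pose fitting.",
  "regions": {
    "head_rigid": [1, 2, 4, 5, 6, 8, 9, 10, 151, 168, 195, 197, 152, 234, 454, 127, 356, 162, 389, 132, 361, 58, 288, 93, 323, 148, 377, 176, 400],
    "left_periocular": [263, 249, 390, 373, 374, 380, 381, 382, 362, 466, 388, 387, 386, 385, 384, 398],
    "right_periocular": [33, 7, 163, 144, 145, 153, 154, 155, 133, 246, 161, 160, 159, 158, 157, 173],
    "perioral": [61, 146, 91, 181, 84, 17, 314, 405, 321, 375, 291, 308, 324, 318, 402, 317, 14, 87, 178, 88, 95, 185, 40, 39, 37, 0, 267, 269, 270, 409, 415, 310, 311, 312, 13, 82, 81, 42, 183, 78]
  }
}
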