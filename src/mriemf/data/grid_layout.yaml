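# Default planar measurement layout for the stray-field map.
# 70 planar points (10 x-columns by 7 y-rows) at 3 heights = 210 positions.
# The mesh uses a 0.20 m step close to the bore axis (x = 2.0 m) and the
# couch side (y >= 3.8 m), a 0.40 m step elsewhere.  Units: metres, room
# frame with origin at the map corner nearest Door A, z up.
step_short: 0.20
step_long: 0.40
heights: [0.72, 1.19, 1.56]
x_columns: &x [0.4, 0.8, 1.2, 1.6, 1.8, 2.0, 2.2, 2.4, 2.8, 3.2]
y_rows: &y [2.6, 3.0, 3.4, 3.8, 4.0, 4.2, 4.4]
planar_points:
  - [0.4, 2.6]
  - [0.4, 3.0]
  - [0.4, 3.4]
  - [0.4, 3.8]
  - [0.4, 4.0]
  - [0.4, 4.2]
  - [0.4, 4.4]
  - [0.8, 2.6]
  - [0.8, 3.0]
  - [0.8, 3.4]
  - [0.8, 3.8]
  - [0.8, 4.0]
  - [0.8, 4.2]
  - [0.8, 4.4]
  - [1.2, 2.6]
  - [1.2, 3.0]
  - [1.2, 3.4]
  - [1.2, 3.8]
  - [1.2, 4.0]
  - [1.2, 4.2]
  - [1.2, 4.4]
  - [1.6, 2.6]
  - [1.6, 3.0]
  - [1.6, 3.4]
  - [1.6, 3.8]
  - [1.6, 4.0]
  - [1.6, 4.2]
  - [1.6, 4.4]
  - [1.8, 2.6]
  - [1.8, 3.0]
  - [1.8, 3.4]
  - [1.8, 3.8]
  - [1.8, 4.0]
  - [1.8, 4.2]
  - [1.8, 4.4]
  - [2.0, 2.6]
  - [2.0, 3.0]
  - [2.0, 3.4]
  - [2.0, 3.8]
  - [2.0, 4.0]
  - [2.0, 4.2]
  - [2.0, 4.4]
  - [2.2, 2.6]
  - [2.2, 3.0]
  - [2.2, 3.4]
  - [2.2, 3.8]
  - [2.2, 4.0]
  - [2.2, 4.2]
  - [2.2, 4.4]
  - [2.4, 2.6]
  - [2.4, 3.0]
  - [2.4, 3.4]
  - [2.4, 3.8]
  - [2.4, 4.0]
  - [2.4, 4.2]
  - [2.4, 4.4]
  - [2.8, 2.6]
  - [2.8, 3.0]
  - [2.8, 3.4]
  - [2.8, 3.8]
  - [2.8, 4.0]
  - [2.8, 4.2]
  - [2.8, 4.4]
  - [3.2, 2.6]
  - [3.2, 3.0]
  - [3.2, 3.4]
  - [3.2, 3.8]
  - [3.2, 4.0]
  - [3.2, 4.2]
  - [3.2, 4.4]
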