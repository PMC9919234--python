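# Training shape: rectangle lap (editable waypoints, metres)
name: rectangle
waypoints:
  - [0.5, 0.5]
  - [4.5, 0.5]
  - [4.5, 3.5]
  - [0.5, 3.5]
  - [0.5, 0.5]
  - [2.5, 0.5]
walking_speed: 0.7
radar_rate: 10.0
depth_rate: 10.0
n_realisations: 40
obstacle_regions: []
depth_sensor_position: [2.5, -1.0]
seed: 0
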