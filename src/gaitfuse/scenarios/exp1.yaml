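# Evaluation scenario: serpentine walk among occluding obstacles
# (radar at 10 Hz, depth at 30 Hz)
name: exp1
waypoints:
  - [0.5, 0.5]
  - [4.5, 0.5]
  - [4.5, 1.5]
  - [0.5, 1.5]
  - [0.5, 2.5]
  - [4.5, 2.5]
  - [4.5, 3.5]
  - [0.5, 3.5]
walking_speed: 0.5
radar_rate: 10.0
depth_rate: 30.0
n_realisations: 10
obstacle_regions:
  - [1.0, 1.7, 1.7, 2.3]
  - [3.2, 0.9, 3.9, 1.4]
depth_sensor_position: [2.5, -1.0]
seed: 0
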