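default_action: 5
rules:
- name: emergency-low
  tier: 1
  windows: [[0, 24]]
  op: '<'
  threshold: 70
  action: 3
- name: fasting-high
  tier: 2
  windows: [[0, 7], [9, 12], [14, 18], [20, 23]]
  op: '>'
  threshold: 126
  action: 1
- name: before-sleep-low
  tier: 3
  windows: [[22, 24]]
  op: '<'
  threshold: 120
  action: 2
- name: post-meal-high
  tier: 4
  windows: [[9, 12], [15, 17], [20, 23]]
  op: '>'
  threshold: 140
  action: 1
- name: post-meal-low
  tier: 4
  windows: [[9, 12], [15, 17], [20, 23]]
  op: '<'
  threshold: 100
  action: 2
- name: always-insulin
  tier: 5
  windows: [[0, 24]]
  op: '>'
  threshold: 180
  action: 4
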