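# The five measured flexion actions: per-muscle MTJ displacement endpoints
# (mm, shortening positive) and, for the resisted actions, the platform
# display reading (N).  Fingertip force = display reading + plate resistance.
plate_resistance: 0.7
actions:
  - action_id: 1
    mode: free
    displacements: {FDS: 18.22, FDP: 22.22, ED: -12.54}
  - action_id: 2
    mode: resisted
    displacements: {FDS: 4.33, FDP: 6.60, ED: 0.0}
    display_reading: 5.0
  - action_id: 3
    mode: resisted
    displacements: {FDS: 10.48, FDP: 12.10, ED: 0.0}
    display_reading: 10.0
  - action_id: 4
    mode: resisted
    displacements: {FDS: 15.88, FDP: 16.30, ED: 0.0}
    display_reading: 15.0
  - action_id: 5
    mode: resisted
    displacements: {FDS: 20.56, FDP: 21.70, ED: 0.0}
    display_reading: 20.0
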