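contact_offset: 0.0
contact_penalty: 1000.0
fingers:
  index:
    joints:
      DIP:
        angle_range:
        - 0.0
        - 1.2217304763960306
        spring_lever_arm: 3.5
      MCP:
        angle_range:
        - 0.0
        - 1.5707963267948966
        spring_lever_arm: 6.0
      PIP:
        angle_range:
        - 0.0
        - 1.7453292519943295
        spring_lever_arm: 5.0
    phalanx_lengths:
    - 45.0
    - 25.0
    - 22.0
  little:
    joints:
      DIP:
        angle_range:
        - 0.0
        - 1.2217304763960306
        spring_lever_arm: 3.5
      MCP:
        angle_range:
        - 0.0
        - 1.5707963267948966
        spring_lever_arm: 6.0
      PIP:
        angle_range:
        - 0.0
        - 1.7453292519943295
        spring_lever_arm: 5.0
    phalanx_lengths:
    - 38.0
    - 20.0
    - 20.0
  middle:
    joints:
      DIP:
        angle_range:
        - 0.0
        - 1.2217304763960306
        spring_lever_arm: 3.5
      MCP:
        angle_range:
        - 0.0
        - 1.5707963267948966
        spring_lever_arm: 6.0
      PIP:
        angle_range:
        - 0.0
        - 1.7453292519943295
        spring_lever_arm: 5.0
    phalanx_lengths:
    - 50.0
    - 30.0
    - 24.0
  ring:
    joints:
      DIP:
        angle_range:
        - 0.0
        - 1.2217304763960306
        spring_lever_arm: 3.5
      MCP:
        angle_range:
        - 0.0
        - 1.5707963267948966
        spring_lever_arm: 6.0
      PIP:
        angle_range:
        - 0.0
        - 1.7453292519943295
        spring_lever_arm: 5.0
    phalanx_lengths:
    - 46.0
    - 28.0
    - 23.0
muscles:
  ED:
    index:
      arm_growth: 0.0
      cross_section_area: 8.0
      free_length: 260.0
      ligament_area: 10.0
      ligament_length: 20.0
      moment_arms:
        DIP: -4.0
        MCP: -10.5
        PIP: -6.0
    little:
      arm_growth: 0.0
      cross_section_area: 8.0
      free_length: 260.0
      ligament_area: 10.0
      ligament_length: 20.0
      moment_arms:
        DIP: -3.36
        MCP: -8.82
        PIP: -5.04
    middle:
      arm_growth: 0.0
      cross_section_area: 8.0
      free_length: 260.0
      ligament_area: 10.0
      ligament_length: 20.0
      moment_arms:
        DIP: -3.92
        MCP: -10.29
        PIP: -5.88
    ring:
      arm_growth: 0.0
      cross_section_area: 8.0
      free_length: 260.0
      ligament_area: 10.0
      ligament_length: 20.0
      moment_arms:
        DIP: -3.68
        MCP: -9.66
        PIP: -5.5200000000000005
  FDP:
    index:
      arm_growth: 0.4
      cross_section_area: 12.0
      free_length: 270.0
      ligament_area: 10.0
      ligament_length: 30.0
      moment_arms:
        DIP: 4.8
        MCP: 10.5
        PIP: 6.5
    little:
      arm_growth: 0.4
      cross_section_area: 12.0
      free_length: 270.0
      ligament_area: 10.0
      ligament_length: 30.0
      moment_arms:
        DIP: 4.032
        MCP: 8.82
        PIP: 5.46
    middle:
      arm_growth: 0.4
      cross_section_area: 12.0
      free_length: 270.0
      ligament_area: 10.0
      ligament_length: 30.0
      moment_arms:
        DIP: 4.704
        MCP: 10.29
        PIP: 6.37
    ring:
      arm_growth: 0.4
      cross_section_area: 12.0
      free_length: 270.0
      ligament_area: 10.0
      ligament_length: 30.0
      moment_arms:
        DIP: 4.416
        MCP: 9.66
        PIP: 5.98
  FDS:
    index:
      arm_growth: 0.25
      cross_section_area: 13.0
      free_length: 230.0
      ligament_area: 10.0
      ligament_length: 15.0
      moment_arms:
        MCP: 11.5
        PIP: 7.0
    little:
      arm_growth: 0.25
      cross_section_area: 13.0
      free_length: 230.0
      ligament_area: 10.0
      ligament_length: 15.0
      moment_arms:
        MCP: 9.66
        PIP: 5.88
    middle:
      arm_growth: 0.25
      cross_section_area: 13.0
      free_length: 230.0
      ligament_area: 10.0
      ligament_length: 15.0
      moment_arms:
        MCP: 11.27
        PIP: 6.859999999999999
    ring:
      arm_growth: 0.25
      cross_section_area: 13.0
      free_length: 230.0
      ligament_area: 10.0
      ligament_length: 15.0
      moment_arms:
        MCP: 10.58
        PIP: 6.44
parameters:
  ip_spring_stiffness: 1.0
  ligament_modulus: 114.03
  mcp_spring_stiffness: 2.0
  tendon_modulus: 125.31
plate_clearance: 0.0
units: N-mm-MPa
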