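# Column schema for loopbarrier CSV artifacts. Names are stable across
# versions; units are encoded in the column names.
loop_track:
  frame: integer frame index (0-based)
  time_s: frame time in seconds
  position_bp: loop spot position along the DNA in base pairs (NaN = no spot)
  loop_size_bp: looped DNA in base pairs (0 = no loop)
  intensity_fraction: excess spot intensity / total DNA intensity
  flag: quality flag ("", no-spot, multi-spot, gap)
spot_track:
  frame: integer frame index (0-based)
  time_s: frame time in seconds
  position_bp: particle position in base pairs (NaN when absent)
  intensity: background-subtracted integrated spot intensity (a.u.)
  present: whether the spot was detected in this frame
dwell_set:
  duration: dwell duration (seconds or minutes, consistent per file)
  censored: true when the molecule outlived the observation
  context: free label (on-DNA, on-glass, loop-colocalization)
event_table:
  event_id: integer event index
  t_start_s: encounter opening time in seconds
  duration_s: co-localization duration in seconds
  force_pn: DNA tension at the encounter in piconewtons
  loop_bp: loop size at the encounter in base pairs
  side: CTCF side faced (N, C) when known
  outcome: blocked | passed | switch | shrink-after-release |
    growing-through | indeterminate
step_list:
  step_time_s: change-point time in seconds
  step_size_nm: plateau difference in nanometres (signed)
  step_size_bp: size converted to base pairs at the clamped force
  dwell_s: time since the previous step in seconds
encounter_table:
  force_pn: bin-centre DNA tension in piconewtons
  blocked: Bernoulli outcome of one encounter
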