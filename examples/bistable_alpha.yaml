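# Bistable regime: tragedy corner vs coexistence edge at maximal cost.
# Used by `coevrisk simulate` (initial state below starts inside the edge
# basin) and by `coevrisk sweep-m` / `coevrisk basins`.
preset: bistable_edge_alpha
integration:
  x0: 0.8
  r0: 0.9
  c0: 0.25
  t_end: 2000.0
grid:
  nx: 21
  nr: 21
  nc: 11
sweep:
  m_values: [2, 3, 4, 5, 6, 7]
  level: alpha
seed: 1
log_level: INFO
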