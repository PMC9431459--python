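# Demo configuration: package defaults with a couple of explicit overrides.
# Any key omitted here falls back to the package default.
groups:
  Cro:
    vmax_nh4: 6.6      # maximum specific NH4+ uptake, d^-1
    vmax_no3: 3.0
    k_nh4: 500.0       # half-saturation, nmol L^-1
    k_no3: 500.0
    mortality: 0.1
    diazotroph_floor: 0.31   # growth sustained by N2 fixation, d^-1
  Oth:
    vmax_nh4: 1.1
    vmax_no3: 0.8
    k_nh4: 50.0
    k_no3: 100.0
    mortality: 0.1
zoo:
  g_max: 1.0           # maximum grazing rate, d^-1
  k_g: 5.0             # grazing half-saturation, nmol L^-1
  m_zoo: 0.1           # quadratic mortality, (nmol L^-1)^-1 d^-1
ecosystem:
  initial: {n_cro: 1.0, n_oth: 1.0, n_zoo: 0.1}
  t_end: 10.0
  dt: 0.01
synthetic:
  seed: 1
  sink_fraction: 0.5   # fraction of drawdown not appearing in biomass
  noise_sigma: 0.1
fit:
  group: Cro
  free:
    vmax_nh4: [1.0, 12.0]
  n_starts: 5
  seed: 0
budget:
  day_start: 0.0
  day_end: 3.0
  mortality: 0.0
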