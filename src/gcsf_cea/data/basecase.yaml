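# Base-case model configuration (2022 NTD).
# Each uncertain parameter appears again under `ranges` (one-way sensitivity
# bounds; 95% CI or plausible band) and `dist_family` (PSA distribution).
# Drug prices are NHI reimbursement prices held fixed in the PSA; their ranges
# span -20% to 0% of the list price because reimbursement prices only adjust
# downwards.  Biosimilars inherit effectiveness from their reference product.

p_fn_cycle1: 0.364
rr_cycle2plus: 0.46
rr_history: 2.4
p_fn_death: 0.036

p_rdi_low_base: 0.247
or_rdi_low: 1.58
hr_rdi_low: 1.73

u_chemo: 0.78
u_fn_decrement: 0.36
u_surv_1_5: 0.84
u_surv_5plus: 0.91

cost_fn_event: 8287
los_fn: 10.53
gcsf_days: 4

annual_bc_mortality: 0.0202
bc_mortality_years: 10
discount_rate: 0.03
wtp: 976914

start_age: 56
n_cycles: 6
cycle_days: 21
age_cap: 110

drugs:
  filgrastim:
    price: 1673
    injections_per_cycle: 4
    rr_cycles_1_2: 0.640
    rr_cycles_3plus: 0.575
  lenograstim:
    price: 1674
    injections_per_cycle: 4
    rr_cycles_1_2: 0.452
    rr_cycles_3plus: 0.609
  pegfilgrastim:
    price: 16626
    injections_per_cycle: 1
    rr_cycles_1_2: 0.334
    rr_cycles_3plus: 0.334
  filgrastim_biosimilar:
    price: 1559
    injections_per_cycle: 4
    reference: filgrastim
  pegfilgrastim_biosimilar:
    price: 14457
    injections_per_cycle: 1
    reference: pegfilgrastim

ranges:
  p_fn_cycle1: [0.293, 0.436]
  rr_cycle2plus: [0.4203, 0.5034]
  rr_history: [2.2, 2.6]
  p_fn_death: [0.029, 0.043]
  rr_filgrastim_c12: [0.5077, 0.8076]
  rr_filgrastim_c3plus: [0.4477, 0.7379]
  rr_lenograstim_c12: [0.2767, 0.7393]
  rr_lenograstim_c3plus: [0.3944, 0.9398]
  rr_pegfilgrastim: [0.2097, 0.5319]
  p_rdi_low_base: [0.149, 0.345]
  or_rdi_low: [1.20, 2.10]
  hr_rdi_low: [1.17, 2.55]
  u_chemo: [0.728, 0.832]
  u_fn_decrement: [0.289, 0.431]
  u_surv_1_5: [0.791, 0.889]
  u_surv_5plus: [0.893, 0.927]
  price_pegfilgrastim: [13301, 16626]
  price_filgrastim: [1338, 1673]
  price_lenograstim: [1339, 1674]
  cost_fn_event: [6630, 9944]
  los_fn: [7.39, 13.67]
  discount_rate: [0.0, 0.05]

dist_family:
  p_fn_cycle1: beta
  rr_cycle2plus: lognormal
  rr_history: lognormal
  p_fn_death: beta
  rr_filgrastim_c12: lognormal
  rr_filgrastim_c3plus: lognormal
  rr_lenograstim_c12: lognormal
  rr_lenograstim_c3plus: lognormal
  rr_pegfilgrastim: lognormal
  p_rdi_low_base: beta
  or_rdi_low: lognormal
  hr_rdi_low: lognormal
  u_chemo: beta
  u_fn_decrement: beta
  u_surv_1_5: beta
  u_surv_5plus: beta
  price_pegfilgrastim: fixed
  price_filgrastim: fixed
  price_lenograstim: fixed
  price_pegfilgrastim_biosimilar: fixed
  price_filgrastim_biosimilar: fixed
  cost_fn_event: gamma
  los_fn: gamma
  discount_rate: fixed
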