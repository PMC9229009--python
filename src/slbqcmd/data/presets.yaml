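# Lipid-system presets for the synthetic QCM-D generator.
# Frequencies are overtone-normalized Hz; dissipation in 1e-6 units; times in
# minutes; rate constants in 1/min.  Values pin the reported behavior of each
# system: PC forms a bilayer in two steps (adsorb to a -72 Hz minimum within
# ~2.5 min, rupture to -26 Hz, dissipation peak 3.5 relaxing to 0.6); PG
# adsorbs slowly for ~40 min into a vesicle layer (-52 Hz, D 3.8, overtones
# spread apart); PG/LPG 10-30% rupture on contact to bilayer plateaus between
# -26 and -29 Hz with low dissipation; PG/LPG 40% stabilizes at -23 Hz and the
# buffer rinse strips lipid (f rises to -18 Hz while D rises to 0.8).
PC:
  scenario: two_step_slb
  f_min: -72.0
  t_min: 2.5
  f_plateau: -26.0
  D_peak: 3.5
  D_final: 0.6
  rate: 2.0
  overtone_spread: 0.5
  markers: {t_start: 5.0, t_rinse: 15.0, t_end: 20.0}
PG:
  scenario: vesicle_layer
  f_plateau: -52.0
  D_final: 3.8
  rate: 0.075
  overtone_spread: 6.0
  markers: {t_start: 5.0, t_rinse: 45.0, t_end: 52.0}
PG-LPG-10:
  scenario: one_step_slb
  f_plateau: -26.0
  D_final: 0.5
  rate: 1.0
  overtone_spread: 0.5
  markers: {t_start: 5.0, t_rinse: 15.0, t_end: 20.0}
PG-LPG-20:
  scenario: one_step_slb
  f_plateau: -27.0
  D_final: 0.6
  rate: 1.0
  overtone_spread: 0.5
  markers: {t_start: 5.0, t_rinse: 15.0, t_end: 20.0}
PG-LPG-30:
  scenario: one_step_slb
  f_plateau: -29.0
  D_final: 0.8
  rate: 0.8
  overtone_spread: 0.5
  markers: {t_start: 5.0, t_rinse: 15.0, t_end: 20.0}
PG-LPG-40:
  scenario: incomplete_bilayer
  f_pre_rinse: -23.0
  f_plateau: -18.0
  D_peak: 0.3
  D_final: 0.8
  rate: 1.0
  rinse_rate: 1.0
  overtone_spread: 0.5
  markers: {t_start: 5.0, t_rinse: 15.0, t_end: 22.0}
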