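{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "slbqcmd analysis report",
  "type": "object",
  "required": ["signature", "packing", "warnings", "config", "version"],
  "properties": {
    "signature": {
      "type": "object",
      "required": ["label", "f_final_Hz", "D_final_1e6", "initial_slope_Hz_per_min",
                   "overtone_spread_final_Hz", "rinse_delta_f_Hz",
                   "rinse_delta_D_1e6", "rigid"],
      "properties": {
        "label": {"type": "string",
                  "enum": ["vesicle_layer", "two_step_slb", "one_step_slb",
                           "incomplete_bilayer", "indeterminate"]},
        "f_final_Hz": {"type": "number"},
        "D_final_1e6": {"type": "number"},
        "initial_slope_Hz_per_min": {"type": "number"},
        "overtone_spread_final_Hz": {"type": "number"},
        "rinse_delta_f_Hz": {"type": "number"},
        "rinse_delta_D_1e6": {"type": "number"},
        "rigid": {"type": "boolean"},
        "f_min_Hz": {"type": ["number", "null"]},
        "t_min_min": {"type": ["number", "null"]},
        "f_pre_rinse_Hz": {"type": ["number", "null"]},
        "D_pre_rinse_1e6": {"type": ["number", "null"]},
        "warnings": {"type": "array", "items": {"type": "string"}}
      }
    },
    "packing": {
      "type": ["object", "null"],
      "required": ["delta_f_Hz", "areal_mass_ng_cm2", "corrected_mass_ng_cm2",
                   "M_L_ng", "N_L_nm2", "a_L_nm2", "v_L_avg_nm3", "h_L_nm"],
      "properties": {
        "delta_f_Hz": {"type": "number"},
        "areal_mass_ng_cm2": {"type": "number"},
        "corrected_mass_ng_cm2": {"type": "number"},
        "mw_avg_g_mol": {"type": "number"},
        "M_L_ng": {"type": "number"},
        "density_total_nm2": {"type": "number"},
        "N_L_nm2": {"type": "number"},
        "a_L_nm2": {"type": "number"},
        "v_L_avg_nm3": {"type": "number"},
        "h_L_nm": {"type": "number"},
        "warnings": {"type": "array", "items": {"type": "string"}}
      }
    },
    "warnings": {"type": "array", "items": {"type": "string"}},
    "config": {"type": "object"},
    "version": {"type": "string"}
  }
}
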