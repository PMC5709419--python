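{
  "description": "Thermodynamic parameters for the five Salmonella metal sensors: dissociation constants in molar, abundances as functional assemblies per cell, DNA targets as operator-promoter copies per cell.",
  "sensors": [
    {
      "name": "Zur",
      "assembly": "dimer",
      "abundance": 21,
      "abundance_sd": 7,
      "dna_targets": 4,
      "mode": "co_repressor",
      "metal_kd": {
        "Co": {"kd_M": 1.5e-8, "bound": "exact", "sd_M": 0.6e-8},
        "Zn": {"kd_M": 6.4e-13, "bound": "exact", "sd_M": 0.4e-13}
      },
      "apo_dna_kd": {"kd_M": 2.7e-5, "bound": "lower", "sd_M": 0.4e-5},
      "holo_dna_kd": {
        "Co": {"kd_M": 3.1e-8, "bound": "exact", "sd_M": 0.3e-8},
        "Zn": {"kd_M": 4.1e-8, "bound": "exact", "sd_M": 1.0e-8}
      },
      "notes": {
        "zn_metal_kd_is_two_site": "The Zn Kd is for the two tightest exchangeable sites (Zn2 form), which suffice to trigger the allosteric switch; the Zn holo DNA Kd is the matching Zn2 value.",
        "zn4_dna_kd_M": 5.4e-8,
        "zn4_dna_sd_M": 1.8e-8
      }
    },
    {
      "name": "ZntR",
      "assembly": "dimer",
      "abundance": 34,
      "abundance_sd": 15,
      "dna_targets": 1,
      "mode": "activator",
      "metal_kd": {
        "Co": {"kd_M": 9.5e-8, "bound": "exact", "sd_M": 1.0e-8},
        "Zn": {"kd_M": 3.2e-12, "bound": "exact", "sd_M": 0.7e-12}
      },
      "apo_dna_kd": {"kd_M": 1.1e-6, "bound": "exact", "sd_M": 0.3e-6},
      "holo_dna_kd": {
        "Co": {"kd_M": 3.4e-7, "bound": "exact", "sd_M": 1.0e-7},
        "Zn": {"kd_M": 6.5e-7, "bound": "exact", "sd_M": 3.3e-7}
      },
      "notes": {
        "averaged_holo_dna_kd_M": 4.7e-7
      }
    },
    {
      "name": "RcnR",
      "assembly": "tetramer",
      "abundance": 22,
      "abundance_sd": 2,
      "dna_targets": 1,
      "mode": "de_repressor",
      "metal_kd": {
        "Co": {"kd_M": 5.1e-10, "bound": "exact", "sd_M": 0.9e-10},
        "Zn": {"kd_M": 9.4e-12, "bound": "exact", "sd_M": 1.0e-12}
      },
      "apo_dna_kd": {"kd_M": 1.5e-7, "bound": "exact", "sd_M": 0.8e-7},
      "holo_dna_kd": {
        "Co": {"kd_M": 1.5e-5, "bound": "lower", "sd_M": 0.2e-5},
        "Zn": {"kd_M": 1.3e-5, "bound": "lower", "sd_M": 0.2e-5}
      }
    },
    {
      "name": "FrmR_E64H",
      "assembly": "tetramer",
      "abundance": 149,
      "abundance_sd": 4,
      "dna_targets": 15,
      "mode": "de_repressor",
      "metal_kd": {
        "Co": {"kd_M": 2.6e-7, "bound": "exact", "sd_M": 0.4e-7},
        "Zn": {"kd_M": 2.3e-11, "bound": "exact", "sd_M": 0.3e-11}
      },
      "apo_dna_kd": {"kd_M": 4.3e-7, "bound": "exact", "sd_M": 0.4e-7},
      "holo_dna_kd": {
        "Co": {"kd_M": 2.3e-6, "bound": "exact", "sd_M": 0.3e-6},
        "Zn": {"kd_M": 3.5e-6, "bound": "exact", "sd_M": 0.7e-6}
      }
    },
    {
      "name": "FrmR",
      "assembly": "tetramer",
      "abundance": 135,
      "abundance_sd": 17,
      "dna_targets": 15,
      "mode": "de_repressor",
      "metal_kd": {
        "Co": {"kd_M": 7.6e-6, "bound": "exact", "sd_M": 0.4e-6},
        "Zn": {"kd_M": 1.7e-10, "bound": "exact", "sd_M": 0.7e-10}
      },
      "apo_dna_kd": {"kd_M": 9.9e-8, "bound": "exact", "sd_M": 0.3e-8},
      "holo_dna_kd": {
        "Zn": {"kd_M": 3.1e-6, "bound": "exact", "sd_M": 0.4e-6}
      },
      "notes": {
        "co_holo_dna_kd": "Not determined directly (the Co affinity of FrmR is too weak); the occupancy model estimates it from the Zn value scaled by the FrmR_E64H Co/Zn fold-difference, giving 2.0e-6 M."
      }
    }
  ]
}
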