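{
  "energy_min_keV": 30.0,
  "energy_max_keV": 3000.0,
  "total_channel_convention": "photoelectric + incoherent (coherent excluded)",
  "brems_endpoint_keV": 2300.0,
  "tc99m_photopeak_keV": 140.5,
  "materials": {
    "water": {
      "density_g_cm3": 1.0,
      "composition": {
        "H": 0.1119,
        "O": 0.8881
      },
      "table": "attenuation_water.csv"
    },
    "air": {
      "density_g_cm3": 0.001205,
      "composition": {
        "N": 0.767,
        "O": 0.233
      },
      "table": "attenuation_air.csv"
    },
    "perpex": {
      "density_g_cm3": 1.19,
      "composition": {
        "H": 0.080538,
        "C": 0.599848,
        "O": 0.319614
      },
      "table": "attenuation_perpex.csv"
    },
    "nai": {
      "density_g_cm3": 3.67,
      "composition": {
        "Na": 0.1534,
        "I": 0.8466
      },
      "table": "attenuation_nai.csv"
    },
    "bgo": {
      "density_g_cm3": 7.13,
      "composition": {
        "Bi": 0.671,
        "Ge": 0.1749,
        "O": 0.1541
      },
      "table": "attenuation_bgo.csv"
    },
    "gso": {
      "density_g_cm3": 6.71,
      "composition": {
        "Gd": 0.7442,
        "Si": 0.0665,
        "O": 0.1893
      },
      "table": "attenuation_gso.csv"
    },
    "cdwo4": {
      "density_g_cm3": 7.9,
      "composition": {
        "Cd": 0.312,
        "W": 0.5103,
        "O": 0.1777
      },
      "table": "attenuation_cdwo4.csv"
    },
    "lead": {
      "density_g_cm3": 11.34,
      "composition": {
        "Pb": 1.0
      },
      "table": "attenuation_lead.csv"
    },
    "tungsten": {
      "density_g_cm3": 19.3,
      "composition": {
        "W": 1.0
      },
      "table": "attenuation_tungsten.csv"
    },
    "tin": {
      "density_g_cm3": 7.31,
      "composition": {
        "Sn": 1.0
      },
      "table": "attenuation_tin.csv"
    }
  }
}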