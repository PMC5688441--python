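{
  "catalogue": [
    {
      "delivery_point": "community",
      "entries": [
        {
          "affected_fraction": 1.0,
          "age_group": "child_1_59m",
          "cause": "pneumonia",
          "effectiveness": 0.8
        }
      ],
      "id": "abx",
      "is_family_planning": false,
      "name": "Oral antibiotics for pneumonia"
    },
    {
      "delivery_point": "cemoc_facility",
      "entries": [
        {
          "affected_fraction": 0.95,
          "age_group": "maternal",
          "cause": "hemorrhage",
          "effectiveness": 0.65
        },
        {
          "affected_fraction": 0.9,
          "age_group": "stillbirth",
          "cause": "intrapartum",
          "effectiveness": 0.6
        }
      ],
      "id": "cemoc_ld",
      "is_family_planning": false,
      "name": "Labor and delivery management (CEmOC level)"
    },
    {
      "delivery_point": "clinic_essential",
      "entries": [],
      "id": "fp",
      "is_family_planning": true,
      "name": "Reducing unmet need for family planning"
    }
  ],
  "causes": [
    {
      "age_group": "maternal",
      "code": "hemorrhage",
      "label": "Antepartum/postpartum hemorrhage"
    },
    {
      "age_group": "stillbirth",
      "code": "intrapartum",
      "label": "Intrapartum stillbirth"
    },
    {
      "age_group": "neonatal_0_1m",
      "code": "sepsis_pneumonia",
      "label": "Neonatal sepsis/pneumonia"
    },
    {
      "age_group": "child_1_59m",
      "code": "pneumonia",
      "label": "Pneumonia"
    }
  ],
  "country": "Öresund Testland",
  "coverage": {
    "abx": 0.2,
    "cemoc_ld": 0.1,
    "fp": 0.3
  },
  "cpr": 0.3,
  "deaths": {
    "hemorrhage": 200.0,
    "intrapartum": 300.0,
    "pneumonia": 1000.0,
    "sepsis_pneumonia": 500.0
  },
  "fp_params": {
    "contraceptive_effectiveness": 0.85,
    "risky_birth_fraction": 0.25,
    "risky_fraction_shift_per_cpr_point": 0.002,
    "risky_relative_risk": 1.5
  },
  "live_births": 100000.0,
  "metadata": {
    "note": "hand-built toy fixture for tests"
  },
  "u5mr": 15.0,
  "units": "proportion",
  "unmet_need": 0.25,
  "women_15_49": 420000.0,
  "year": 2016
}
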