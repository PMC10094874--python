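{
  "schema": "tba-tree v1",
  "nodes": [
    {
      "id": "dcm",
      "label": "Original DCM extract",
      "role": "extract",
      "parent_id": null,
      "solvent": "DCM",
      "weight": {
        "value": 4.0,
        "unit": "g"
      },
      "potency": {
        "ic50": {
          "value": 0.01409,
          "unit": "g/L"
        },
        "censored": "none"
      }
    },
    {
      "id": "f01",
      "label": "F-1",
      "role": "fraction",
      "parent_id": "dcm",
      "weight": {
        "value": 0.0018000000000000002,
        "unit": "g"
      },
      "potency": {
        "ic50": {
          "value": 0.0688,
          "unit": "g/L"
        },
        "censored": "none"
      }
    },
    {
      "id": "f02",
      "label": "F-2",
      "role": "fraction",
      "parent_id": "dcm",
      "weight": {
        "value": 0.0094,
        "unit": "g"
      },
      "potency": {
        "ic50": {
          "value": 0.057,
          "unit": "g/L"
        },
        "censored": "none"
      }
    },
    {
      "id": "f03",
      "label": "F-3",
      "role": "fraction",
      "parent_id": "dcm",
      "weight": {
        "value": 0.0092,
        "unit": "g"
      },
      "potency": {
        "ic50": {
          "value": 0.062200000000000005,
          "unit": "g/L"
        },
        "censored": "none"
      }
    },
    {
      "id": "f04",
      "label": "F-4",
      "role": "fraction",
      "parent_id": "dcm",
      "weight": {
        "value": 0.0066,
        "unit": "g"
      },
      "retention_time": {
        "value": 24.7,
        "unit": "min"
      },
      "potency": {
        "ic50": {
          "value": 0.0441,
          "unit": "g/L"
        },
        "censored": "none"
      }
    },
    {
      "id": "f05",
      "label": "F-5",
      "role": "fraction",
      "parent_id": "dcm",
      "weight": {
        "value": 0.006900000000000001,
        "unit": "g"
      },
      "potency": {
        "ic50": {
          "value": 0.0358,
          "unit": "g/L"
        },
        "censored": "none"
      }
    },
    {
      "id": "f06",
      "label": "F-6",
      "role": "fraction",
      "parent_id": "dcm",
      "weight": {
        "value": 0.007,
        "unit": "g"
      },
      "potency": {
        "ic50": {
          "value": 0.036000000000000004,
          "unit": "g/L"
        },
        "censored": "none"
      }
    },
    {
      "id": "f07",
      "label": "F-7",
      "role": "fraction",
      "parent_id": "dcm",
      "weight": {
        "value": 0.0035,
        "unit": "g"
      },
      "potency": {
        "ic50": {
          "value": 0.0256,
          "unit": "g/L"
        },
        "censored": "none"
      }
    },
    {
      "id": "f08",
      "label": "F-8",
      "role": "fraction",
      "parent_id": "dcm",
      "weight": {
        "value": 0.0045000000000000005,
        "unit": "g"
      },
      "retention_time": {
        "value": 39.1,
        "unit": "min"
      },
      "potency": {
        "ic50": {
          "value": 0.0159,
          "unit": "g/L"
        },
        "censored": "none"
      }
    },
    {
      "id": "f09",
      "label": "F-9",
      "role": "fraction",
      "parent_id": "dcm",
      "weight": {
        "value": 0.004,
        "unit": "g"
      },
      "retention_time": {
        "value": 41.7,
        "unit": "min"
      },
      "potency": {
        "ic50": {
          "value": 0.0162,
          "unit": "g/L"
        },
        "censored": "none"
      }
    },
    {
      "id": "f10",
      "label": "F-10",
      "role": "fraction",
      "parent_id": "dcm",
      "weight": {
        "value": 0.0066,
        "unit": "g"
      },
      "potency": {
        "ic50": {
          "value": 0.016300000000000002,
          "unit": "g/L"
        },
        "censored": "none"
      }
    },
    {
      "id": "f11",
      "label": "F-11",
      "role": "fraction",
      "parent_id": "dcm",
      "weight": {
        "value": 0.0108,
        "unit": "g"
      },
      "potency": {
        "ic50": {
          "value": 0.0171,
          "unit": "g/L"
        },
        "censored": "none"
      }
    },
    {
      "id": "f12",
      "label": "F-12",
      "role": "fraction",
      "parent_id": "dcm",
      "weight": {
        "value": 0.012,
        "unit": "g"
      },
      "potency": {
        "ic50": {
          "value": 0.0145,
          "unit": "g/L"
        },
        "censored": "none"
      }
    },
    {
      "id": "f13",
      "label": "F-13",
      "role": "fraction",
      "parent_id": "dcm",
      "weight": {
        "value": 0.004900000000000001,
        "unit": "g"
      },
      "potency": {
        "ic50": {
          "value": 0.0086,
          "unit": "g/L"
        },
        "censored": "none"
      }
    },
    {
      "id": "f14",
      "label": "F-14",
      "role": "fraction",
      "parent_id": "dcm",
      "weight": {
        "value": 0.0035,
        "unit": "g"
      },
      "potency": {
        "ic50": {
          "value": 0.0103,
          "unit": "g/L"
        },
        "censored": "none"
      }
    },
    {
      "id": "f15",
      "label": "F-15",
      "role": "fraction",
      "parent_id": "dcm",
      "weight": {
        "value": 0.0021000000000000003,
        "unit": "g"
      },
      "retention_time": {
        "value": 50.3,
        "unit": "min"
      },
      "potency": {
        "ic50": {
          "value": 0.0083,
          "unit": "g/L"
        },
        "censored": "none"
      }
    },
    {
      "id": "f16",
      "label": "F-16",
      "role": "fraction",
      "parent_id": "dcm",
      "weight": {
        "value": 0.0057,
        "unit": "g"
      },
      "potency": {
        "ic50": {
          "value": 0.0115,
          "unit": "g/L"
        },
        "censored": "none"
      }
    },
    {
      "id": "f17",
      "label": "F-17",
      "role": "fraction",
      "parent_id": "dcm",
      "weight": {
        "value": 0.006,
        "unit": "g"
      },
      "potency": {
        "ic50": {
          "value": 0.0067,
          "unit": "g/L"
        },
        "censored": "none"
      }
    }
  ]
}
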