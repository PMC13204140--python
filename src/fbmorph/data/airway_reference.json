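{
  "version": "1.0",
  "description": "Approximate normative pediatric airway dimensions (anatomical reference for a young child, not patient-specific).",
  "sites": [
    {
      "site": "glottis",
      "ap_mean_mm": 9.8,
      "ap_sd_mm": 1.1,
      "transverse_mean_mm": 3.4,
      "transverse_sd_mm": 0.9,
      "cross_section_mm2": 26.5,
      "source": "plain radiography, children <= 4 years"
    },
    {
      "site": "subglottis",
      "ap_mean_mm": 8.5,
      "ap_sd_mm": 0.6,
      "transverse_mean_mm": 5.6,
      "transverse_sd_mm": 0.8,
      "cross_section_mm2": 38.1,
      "source": "plain radiography, children <= 4 years"
    },
    {
      "site": "cricoid",
      "ap_mean_mm": 7.4,
      "transverse_mean_mm": 6.8,
      "cross_section_mm2": 40.5,
      "source": "plain radiography, children <= 4 years"
    },
    {
      "site": "proximal_trachea",
      "sex_specific_diameter_mm": {"male": 7.3, "female": 6.5},
      "source": "ultrasonography, median diameter, 2-year-olds"
    }
  ],
  "ett": {
    "internal_mm": [4.0, 4.5],
    "outer_mm": [5.3, 6.0],
    "source": "endotracheal tube guideline for 2-year-olds"
  },
  "context_notes": [
    "CT/MR: glottic anteroposterior diameter 7-11 mm and subglottic/tracheal 8-9 mm in children under 2 years.",
    "Each 1 mm reduction in airway diameter (e.g. 6 mm to 5 mm) halves the cross-sectional area and doubles resistance.",
    "Ultrasonography reports a mean cricoid diameter of 7.41 mm."
  ]
}
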