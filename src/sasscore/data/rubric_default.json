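{
  "version": "default-1.0",
  "_comment": "Default SAS severity rubric. Fifteen ordinal clinical categories grouped into neurodevelopmental and systemic subscales; per-category maxima lie in [2, 5] and sum to 47. Category names follow the clinical domains reported for the syndrome; the 'hearing' category is a placeholder for the fifteenth rubric item and the per-category maxima are documented defaults that can be replaced by supplying a different schema file.",
  "categories": [
    {
      "name": "cognitive_adaptive",
      "group": "neurodevelopmental",
      "max_points": 5,
      "level_labels": [
        "average or above cognitive/adaptive function",
        "borderline impairment",
        "mild impairment",
        "moderate impairment",
        "severe impairment",
        "profound impairment"
      ]
    },
    {
      "name": "verbal",
      "group": "neurodevelopmental",
      "max_points": 5,
      "level_labels": [
        "full sentences, age-appropriate",
        "short sentences",
        "many single words",
        "few single words",
        "rare word approximations",
        "nonverbal"
      ]
    },
    {
      "name": "expressive_communication",
      "group": "neurodevelopmental",
      "max_points": 4,
      "level_labels": [
        "effective expressive communication",
        "communicates with minor support",
        "augmentative device or signs, effective",
        "limited intentional communication",
        "no reliable expressive communication"
      ]
    },
    {
      "name": "ambulation",
      "group": "neurodevelopmental",
      "max_points": 3,
      "level_labels": [
        "walks independently, age-appropriate",
        "walks with mild gait abnormality",
        "walks with support or device",
        "non-ambulatory"
      ]
    },
    {
      "name": "behavior",
      "group": "neurodevelopmental",
      "max_points": 3,
      "level_labels": [
        "no significant behavioral concerns",
        "behavioral concerns, no medication",
        "behavior requiring medication",
        "severe behavior requiring inpatient or multiple medications"
      ]
    },
    {
      "name": "sleep",
      "group": "neurodevelopmental",
      "max_points": 3,
      "level_labels": [
        "no sleep difficulties",
        "sleep difficulties, no medication",
        "sleep medication required",
        "refractory sleep disturbance on multiple medications"
      ]
    },
    {
      "name": "sialorrhea",
      "group": "neurodevelopmental",
      "max_points": 2,
      "level_labels": [
        "no drooling",
        "intermittent drooling",
        "persistent drooling or treatment required"
      ]
    },
    {
      "name": "palate",
      "group": "systemic",
      "max_points": 3,
      "level_labels": [
        "normal palate",
        "high-arched palate or bifid uvula",
        "cleft palate, repaired without complication",
        "cleft palate with complications or multiple surgeries"
      ]
    },
    {
      "name": "feeding_growth",
      "group": "systemic",
      "max_points": 4,
      "level_labels": [
        "no feeding or growth concerns",
        "feeding difficulties, managed orally",
        "growth failure or thickened feeds",
        "gastrostomy tube, partial use",
        "fully tube-dependent"
      ]
    },
    {
      "name": "seizure",
      "group": "systemic",
      "max_points": 3,
      "level_labels": [
        "no seizures",
        "seizures, controlled on one medication",
        "seizures on multiple medications",
        "refractory epilepsy or epileptic encephalopathy"
      ]
    },
    {
      "name": "dental",
      "group": "systemic",
      "max_points": 3,
      "level_labels": [
        "no significant dental anomalies",
        "dental anomalies, no intervention",
        "dental anomalies requiring procedures",
        "severe dentition problems, repeated surgical care"
      ]
    },
    {
      "name": "bone",
      "group": "systemic",
      "max_points": 3,
      "level_labels": [
        "normal bone density, no fractures",
        "low bone density, no treatment",
        "osteoporosis or fracture",
        "recurrent fractures or bone-targeted medication"
      ]
    },
    {
      "name": "scoliosis",
      "group": "systemic",
      "max_points": 2,
      "level_labels": [
        "no scoliosis",
        "scoliosis, monitored",
        "scoliosis requiring bracing or surgery"
      ]
    },
    {
      "name": "strabismus",
      "group": "systemic",
      "max_points": 2,
      "level_labels": [
        "no strabismus",
        "strabismus, conservative management",
        "strabismus requiring surgery"
      ]
    },
    {
      "name": "hearing",
      "group": "systemic",
      "max_points": 2,
      "level_labels": [
        "normal hearing",
        "conductive or mild hearing loss",
        "hearing loss requiring amplification"
      ],
      "placeholder": true
    }
  ]
}
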