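# Default diagnosis-category map for the comorbidity pipeline.
#
# Physical categories are ICD-9-CM chapter ranges over the 3-digit code root
# (inclusive).  Psychiatric categories are explicit dotted-code prefixes: a
# code belongs to the category when it equals a prefix or extends it with
# further decimal digits.  The index disorder (borderline personality
# disorder, 301.83) is outside every physical range and every psychiatric
# prefix set by construction.
#
# The psychiatric groupings are conventional, not canonical; substitute your
# own file via `load_category_map(path)` if your coding practice differs.

index_code: "301.83"
index_label: "BPD"

physical:
  - name: "Infectious and parasitic"
    ranges: [[1, 139]]
    representative_codes: ["008.8", "034.0", "110.9"]
  - name: "Neoplasm"
    ranges: [[140, 239]]
    representative_codes: ["174.9", "211.3", "216.9"]
  - name: "Endocrine, metabolic and immunity"
    ranges: [[240, 279]]
    representative_codes: ["244.9", "250.00", "272.4"]
  - name: "Blood and blood-forming organs"
    ranges: [[280, 289]]
    representative_codes: ["280.9", "285.9", "287.5"]
  - name: "Nervous system and sense organs"
    ranges: [[320, 389]]
    representative_codes: ["346.9", "366.9", "381.01"]
  - name: "Circulatory system"
    ranges: [[390, 459]]
    representative_codes: ["401.9", "427.31", "455.6"]
  - name: "Respiratory system"
    ranges: [[460, 519]]
    representative_codes: ["460", "465.9", "486"]
  - name: "Digestive system"
    ranges: [[520, 579]]
    representative_codes: ["521.00", "535.50", "564.00"]
  - name: "Genitourinary system"
    ranges: [[580, 629]]
    representative_codes: ["592.0", "599.0", "626.2"]
  - name: "Skin and subcutaneous tissue"
    ranges: [[680, 709]]
    representative_codes: ["682.9", "691.8", "706.1"]
  - name: "Musculoskeletal system"
    ranges: [[710, 739]]
    representative_codes: ["715.90", "724.2", "729.1"]
  - name: "Congenital anomalies"
    ranges: [[740, 759]]
    representative_codes: ["745.5", "750.0", "754.0"]
  - name: "Injury and poisoning"
    ranges: [[800, 999]]
    representative_codes: ["845.00", "959.9", "999.9"]

psychiatric:
  "Depressive disorder":
    prefixes: ["296.2", "296.3", "300.4", "311"]
    representative_codes: ["296.20", "296.30", "300.4", "311"]
  "Bipolar disorder":
    prefixes: ["296.0", "296.1", "296.4", "296.5", "296.6", "296.7", "296.8"]
    representative_codes: ["296.40", "296.60", "296.7", "296.80"]
  "Anxiety disorder":
    prefixes: ["300.0", "300.2", "300.3", "308.3", "309.81"]
    representative_codes: ["300.00", "300.02", "300.21", "308.3"]
  # Sleep representative codes deliberately avoid the 327 organic-sleep block,
  # whose root also falls in the nervous-system chapter range.
  "Sleep disorder":
    prefixes: ["307.4", "327", "780.5"]
    representative_codes: ["307.41", "307.42", "780.50", "780.52"]
  "Alcohol use disorder":
    prefixes: ["303", "305.0"]
    representative_codes: ["303.90", "305.00"]
  "Opioid use disorder":
    prefixes: ["304.0", "305.5"]
    representative_codes: ["304.00", "305.50"]
  "Amphetamine use disorder":
    prefixes: ["304.4", "305.7"]
    representative_codes: ["304.40", "305.70"]
  # Union of the three substance subtypes above.
  "Substance use disorder":
    prefixes: ["303", "305.0", "304.0", "305.5", "304.4", "305.7"]
    representative_codes: []
  "ADHD":
    prefixes: ["314"]
    representative_codes: ["314.00", "314.01"]
  "Mental retardation":
    prefixes: ["317", "318", "319"]
    representative_codes: ["317", "318.0", "319"]
  "Autistic spectrum disorder":
    prefixes: ["299"]
    representative_codes: ["299.00"]
  "Eating disorder":
    prefixes: ["307.1", "307.5"]
    representative_codes: ["307.1", "307.51"]

# Item universe used for association rule mining (the index label is added
# to case transactions separately).  Substance subtypes are represented only
# through their union so that trivial subtype->union rules are not mined.
arm_items:
  - "Depressive disorder"
  - "Bipolar disorder"
  - "Anxiety disorder"
  - "Sleep disorder"
  - "Substance use disorder"
  - "Eating disorder"
  - "Autistic spectrum disorder"
  - "Mental retardation"
  - "ADHD"
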