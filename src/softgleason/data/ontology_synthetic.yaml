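# Canonical three-level explanation ontology for Gleason pattern grading.
#
# SYNTHETIC TRANSCRIPTION: the explanation classes are the nine ISUP/WHO-aligned
# histological criteria commonly used to justify Gleason patterns 3-5; the
# sub-explanation wording is this package's own paraphrase of the standard
# Iczkowski-style criteria, written for testing and for the synthetic cohort
# generator.  It is not a verbatim copy of any clinical annotation protocol.
#
# Levels: pattern -> explanation -> sub_explanation, plus a benign class that
# exists at every level.  Children are indexed in file order; patterns ascend
# GP3 < GP4 < GP5; benign is always last.
nodes:
  # ---- Gleason patterns -------------------------------------------------
  - term_id: GP3
    level: pattern
    short_name: "Gleason 3"
    long_text: "Gleason pattern 3: discrete, well-formed glandular units"
    color: [0, 104, 0]
  - term_id: GP4
    level: pattern
    short_name: "Gleason 4"
    long_text: "Gleason pattern 4: poorly formed, fused, cribriform or glomeruloid glands"
    color: [0, 0, 139]
  - term_id: GP5
    level: pattern
    short_name: "Gleason 5"
    long_text: "Gleason pattern 5: essentially no gland formation, with or without comedonecrosis"
    color: [139, 0, 0]

  # ---- Explanations: Gleason pattern 3 ---------------------------------
  - term_id: individual_glands
    level: explanation
    parent: GP3
    short_name: "individual glands"
    long_text: "Individual, discrete, well-formed glands"
    color: [46, 139, 87]
  - term_id: compressed_glands
    level: explanation
    parent: GP3
    short_name: "compressed glands"
    long_text: "Compressed or angular discrete glands"
    color: [102, 205, 170]

  # ---- Explanations: Gleason pattern 4 ----------------------------------
  - term_id: poorly_formed_glands
    level: explanation
    parent: GP4
    short_name: "poorly formed glands"
    long_text: "Poorly formed glands with incompletely developed lumina"
    color: [30, 144, 255]
  - term_id: fused_glands
    level: explanation
    parent: GP4
    short_name: "fused glands"
    long_text: "Fused glands without intervening stroma"
    color: [70, 130, 180]
  - term_id: cribriform_glands
    level: explanation
    parent: GP4
    short_name: "cribriform glands"
    long_text: "Cribriform glands with sieve-like perforated epithelium"
    color: [100, 149, 237]
  - term_id: glomeruloid_glands
    level: explanation
    parent: GP4
    short_name: "glomeruloid glands"
    long_text: "Glomeruloid glands with intraluminal cellular tufts"
    color: [135, 206, 250]

  # ---- Explanations: Gleason pattern 5 ----------------------------------
  - term_id: single_cells
    level: explanation
    parent: GP5
    short_name: "single cells"
    long_text: "Single infiltrating tumor cells or cords without gland formation"
    color: [220, 20, 60]
  - term_id: solid_groups
    level: explanation
    parent: GP5
    short_name: "solid groups"
    long_text: "Solid groups or sheets of tumor cells"
    color: [205, 92, 92]
  - term_id: comedonecrosis
    level: explanation
    parent: GP5
    short_name: "comedonecrosis"
    long_text: "Presence of comedonecrosis"
    color: [255, 99, 71]

  # ---- Sub-explanations -------------------------------------------------
  - term_id: individual_glands_open
    level: sub_explanation
    parent: individual_glands
    short_name: "open-lumen glands"
    long_text: "Discrete glands of intermediate size with open, well-defined lumina"
    color: [34, 139, 34]
  - term_id: individual_glands_small
    level: sub_explanation
    parent: individual_glands
    short_name: "small infiltrating glands"
    long_text: "Small, well-formed glands infiltrating between benign glands"
    color: [60, 179, 113]
  - term_id: individual_glands_branching
    level: sub_explanation
    parent: individual_glands
    short_name: "branching glands"
    long_text: "Branching glands with well-defined lumina"
    color: [0, 128, 0]
  - term_id: compressed_glands_elongated
    level: sub_explanation
    parent: compressed_glands
    short_name: "elongated compressed glands"
    long_text: "Compressed, elongated glands with narrowed lumina"
    color: [144, 238, 144]
  - term_id: compressed_glands_angular
    level: sub_explanation
    parent: compressed_glands
    short_name: "angular glands"
    long_text: "Angular, irregularly contoured discrete glands"
    color: [152, 251, 152]

  - term_id: poorly_formed_incomplete
    level: sub_explanation
    parent: poorly_formed_glands
    short_name: "incomplete lumina"
    long_text: "Glands with poorly formed, incompletely developed lumina"
    color: [65, 105, 225]
  - term_id: poorly_formed_clear_cells
    level: sub_explanation
    parent: poorly_formed_glands
    short_name: "clear-cell clusters"
    long_text: "Poorly formed lumens, cells with clear cytoplasm lying next to each other without true definition of the gland"
    color: [0, 191, 255]
  - term_id: fused_glands_chains
    level: sub_explanation
    parent: fused_glands
    short_name: "microacinar chains"
    long_text: "Fused microacinar glands forming chains"
    color: [95, 158, 160]
  - term_id: fused_glands_confluent
    level: sub_explanation
    parent: fused_glands
    short_name: "confluent glands"
    long_text: "Confluent glandular masses without intervening stroma"
    color: [72, 61, 139]
  - term_id: cribriform_large
    level: sub_explanation
    parent: cribriform_glands
    short_name: "large cribriform"
    long_text: "Large cribriform glands with sieve-like lumina"
    color: [123, 104, 238]
  - term_id: cribriform_small
    level: sub_explanation
    parent: cribriform_glands
    short_name: "small cribriform"
    long_text: "Small cribriform glands with rounded contour"
    color: [106, 90, 205]
  - term_id: glomeruloid_tufts
    level: sub_explanation
    parent: glomeruloid_glands
    short_name: "glomeruloid tufts"
    long_text: "Glands with intraluminal cellular tufts resembling renal glomeruli"
    color: [176, 196, 222]

  - term_id: single_cells_infiltrating
    level: sub_explanation
    parent: single_cells
    short_name: "infiltrating single cells"
    long_text: "Infiltrating single tumor cells without gland formation"
    color: [178, 34, 34]
  - term_id: single_cells_cords
    level: sub_explanation
    parent: single_cells
    short_name: "cords"
    long_text: "Cords of tumor cells without lumen formation"
    color: [233, 150, 122]
  - term_id: single_cells_vacuoles
    level: sub_explanation
    parent: single_cells
    short_name: "vacuolated single cells"
    long_text: "Single tumor cells with intracytoplasmic vacuoles (signet-ring-like)"
    color: [250, 128, 114]
  - term_id: solid_groups_nests
    level: sub_explanation
    parent: solid_groups
    short_name: "solid nests"
    long_text: "Solid nests of tumor cells without lumina"
    color: [165, 42, 42]
  - term_id: solid_groups_sheets
    level: sub_explanation
    parent: solid_groups
    short_name: "solid sheets"
    long_text: "Solid sheets of tumor cells without lumina"
    color: [240, 128, 128]
  - term_id: solid_groups_medullary
    level: sub_explanation
    parent: solid_groups
    short_name: "medullary sheets"
    long_text: "Medullary-like sheets with indistinct cell borders"
    color: [255, 160, 122]
  - term_id: comedonecrosis_central
    level: sub_explanation
    parent: comedonecrosis
    short_name: "central necrosis"
    long_text: "Central necrotic debris within cribriform or solid glands"
    color: [255, 69, 0]

  # ---- Benign -----------------------------------------------------------
  - term_id: benign
    level: benign
    short_name: "benign tissue"
    long_text: "Benign tissue (no tumor pattern annotated)"
    color: [222, 203, 228]
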