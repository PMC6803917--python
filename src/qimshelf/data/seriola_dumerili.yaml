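# QIM demerit-point scheme for whole ice-stored greater amberjack (Seriola dumerili).
# Four quality attribute groups, nine scored parameters, 25 demerit points total.
name: "Seriola dumerili (greater amberjack), whole, on ice"
groups:
  - label: Appearance
    parameters:
      - name: skin
        descriptors:
          - {score: 0, text: "Very bright and iridescent; side brownish (>50% covered)"}
          - {score: 1, text: "Bright; side brownish (<50% covered)"}
          - {score: 2, text: "Pale and dull; side greyish; mouth or operculum reddish-pink"}
          - {score: 3, text: "Marked; superficial mucus; blood on operculum and mouth"}
      - name: anus
        descriptors:
          - {score: 0, text: "Clean and closed"}
          - {score: 1, text: "Abundant yellow feces"}
          - {score: 2, text: "Dry light brown feces and open"}
      - name: odor
        descriptors:
          - {score: 0, text: "Sea, seaweed"}
          - {score: 1, text: "Neutral"}
          - {score: 2, text: "Rancid; metallic"}
          - {score: 3, text: "Putrid"}
  - label: Texture
    parameters:
      - name: firmness
        descriptors:
          - {score: 0, text: "In rigor mortis"}
          - {score: 1, text: "Firm, recovers shape fast (<=2 sec)"}
          - {score: 2, text: "Softness; recovers shape slow (>2 sec)"}
          - {score: 3, text: "Clearly marked and spongy"}
  - label: Eyes
    parameters:
      - name: eye_color
        descriptors:
          - {score: 0, text: "Black; shiny"}
          - {score: 1, text: "Black opaque/slightly milky"}
          - {score: 2, text: "Greyish/milky"}
          - {score: 3, text: "White/grey in partial or total eye"}
      - name: eye_shape
        descriptors:
          - {score: 0, text: "Convex"}
          - {score: 1, text: "Flat"}
          - {score: 2, text: "Concave"}
  - label: Gills
    parameters:
      - name: gill_color
        descriptors:
          - {score: 0, text: "Dark red"}
          - {score: 1, text: "Light red"}
          - {score: 2, text: "Brownish red"}
          - {score: 3, text: "Brown, grey, or discolored; bacteria present"}
      - name: gill_mucus
        descriptors:
          - {score: 0, text: "Absent"}
          - {score: 1, text: "Present and colorless"}
          - {score: 2, text: "Whitish/cream"}
          - {score: 3, text: "Abundant, brown, or yellowish"}
      - name: gill_odor
        descriptors:
          - {score: 0, text: "Sea or seaweed"}
          - {score: 1, text: "Neutral"}
          - {score: 2, text: "Rancid; metallic"}
          - {score: 3, text: "Putrid"}
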