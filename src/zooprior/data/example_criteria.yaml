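# Example criteria and categorical questions for zoonotic disease
# prioritization, with one chosen question per criterion and a sample
# disease list. A facilitated group should adapt criteria, questions,
# cut points and data sources to its own purpose and jurisdiction.
metadata:
  purpose: "Example criteria/question library for zoonotic disease prioritization"
  jurisdiction: "example"
criteria:
  - id: transmission
    label: "Transmission potential between humans and animals"
    question: "Has the zoonotic disease caused outbreaks in the country involving animals and humans within the last 5 years?"
    source: "Country outbreak and surveillance data"
    scale:
      kind: binomial
      categories: ["no", "yes"]
      full_score_category: "yes"
  - id: epidemic_pandemic
    label: "Epidemic/pandemic potential in humans"
    question: "Is the pathogen capable of sustained human-to-human transmission?"
    source: "WHO website; published literature"
    scale:
      kind: multinomial
      categories: ["never reported", "rare/close contact only", "sustained"]
  - id: bioterrorism
    label: "Bioterrorism potential"
    question: "Is the pathogen listed as a select agent (Lists A, B, or C)?"
    source: "CDC website"
    scale:
      kind: binomial
      categories: ["no", "yes"]
      full_score_category: "yes"
  - id: collaborate
    label: "Amenability to collaborate/collaboration already established"
    question: "Do the Ministry of Health (MoH) and Ministry of Agriculture (MoA) have surveillance or control measures for the disease?"
    source: "Ministry programme records"
    scale:
      kind: multinomial
      categories: ["neither", "either MoH or MoA", "both MoH and MoA"]
  - id: economic
    label: "Economic burden of disease"
    question: "What is the case fatality rate in animals without treatment?"
    source: "OIE website; published literature"
    scale:
      kind: multinomial
      categories: ["0-1%", ">1-10%", ">10-25%", ">25%"]
  - id: severity
    label: "Severity of illness in humans"
    question: "What is the case fatality rate in humans without treatment?"
    source: "WHO website; published literature"
    scale:
      kind: multinomial
      categories: ["0-1%", ">1-10%", ">10%"]
  - id: prevent_control
    label: "Ability to prevent/control the zoonotic disease in the country"
    question: "Is the disease listed in country-specific surveillance programs for humans or animals?"
    source: "Country surveillance programme listings"
    scale:
      kind: multinomial
      categories: ["neither", "human or animal", "both human and animal"]
diseases:
  - "Rabies"
  - "Anthrax"
  - "Brucellosis"
  - "Bovine tuberculosis"
  - "Leptospirosis"
  - "Q fever"
  - "Rift Valley fever"
  - "Highly pathogenic avian influenza"
  - "Echinococcosis"
  - "Cysticercosis"
  - "Toxoplasmosis"
  - "Leishmaniasis"
  - "Plague"
  - "Tularemia"
  - "Hantavirus infection"
  - "Nipah virus infection"
  - "Crimean-Congo haemorrhagic fever"
  - "Bacterial Food-Borne Zoonoses"
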