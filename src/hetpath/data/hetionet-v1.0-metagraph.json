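{
  "metanodes": [
    {"identifier": "Anatomy", "abbreviation": "A"},
    {"identifier": "Biological Process", "abbreviation": "BP"},
    {"identifier": "Cellular Component", "abbreviation": "CC"},
    {"identifier": "Compound", "abbreviation": "C"},
    {"identifier": "Disease", "abbreviation": "D"},
    {"identifier": "Gene", "abbreviation": "G"},
    {"identifier": "Molecular Function", "abbreviation": "MF"},
    {"identifier": "Pathway", "abbreviation": "PW"},
    {"identifier": "Pharmacologic Class", "abbreviation": "PC"},
    {"identifier": "Side Effect", "abbreviation": "SE"},
    {"identifier": "Symptom", "abbreviation": "S"}
  ],
  "metaedges": [
    {"source": "Anatomy", "target": "Gene", "kind": "downregulates", "abbreviation": "d", "directed": false},
    {"source": "Anatomy", "target": "Gene", "kind": "expresses", "abbreviation": "e", "directed": false},
    {"source": "Anatomy", "target": "Gene", "kind": "upregulates", "abbreviation": "u", "directed": false},
    {"source": "Compound", "target": "Gene", "kind": "binds", "abbreviation": "b", "directed": false},
    {"source": "Compound", "target": "Side Effect", "kind": "causes", "abbreviation": "c", "directed": false},
    {"source": "Compound", "target": "Gene", "kind": "downregulates", "abbreviation": "d", "directed": false},
    {"source": "Compound", "target": "Disease", "kind": "palliates", "abbreviation": "p", "directed": false},
    {"source": "Compound", "target": "Compound", "kind": "resembles", "abbreviation": "r", "directed": false},
    {"source": "Compound", "target": "Disease", "kind": "treats", "abbreviation": "t", "directed": false},
    {"source": "Compound", "target": "Gene", "kind": "upregulates", "abbreviation": "u", "directed": false},
    {"source": "Disease", "target": "Gene", "kind": "associates", "abbreviation": "a", "directed": false},
    {"source": "Disease", "target": "Gene", "kind": "downregulates", "abbreviation": "d", "directed": false},
    {"source": "Disease", "target": "Anatomy", "kind": "localizes", "abbreviation": "l", "directed": false},
    {"source": "Disease", "target": "Symptom", "kind": "presents", "abbreviation": "p", "directed": false},
    {"source": "Disease", "target": "Disease", "kind": "resembles", "abbreviation": "r", "directed": false},
    {"source": "Disease", "target": "Gene", "kind": "upregulates", "abbreviation": "u", "directed": false},
    {"source": "Gene", "target": "Gene", "kind": "covaries", "abbreviation": "c", "directed": false},
    {"source": "Gene", "target": "Gene", "kind": "interacts", "abbreviation": "i", "directed": false},
    {"source": "Gene", "target": "Biological Process", "kind": "participates", "abbreviation": "p", "directed": false},
    {"source": "Gene", "target": "Cellular Component", "kind": "participates", "abbreviation": "p", "directed": false},
    {"source": "Gene", "target": "Molecular Function", "kind": "participates", "abbreviation": "p", "directed": false},
    {"source": "Gene", "target": "Pathway", "kind": "participates", "abbreviation": "p", "directed": false},
    {"source": "Gene", "target": "Gene", "kind": "regulates", "abbreviation": "r", "directed": true},
    {"source": "Pharmacologic Class", "target": "Compound", "kind": "includes", "abbreviation": "i", "directed": false}
  ],
  "node_counts": {
    "Anatomy": 402,
    "Biological Process": 11381,
    "Cellular Component": 1391,
    "Compound": 1552,
    "Disease": 137,
    "Gene": 20945,
    "Molecular Function": 2884,
    "Pathway": 1822,
    "Pharmacologic Class": 345,
    "Side Effect": 5734,
    "Symptom": 438
  }
}
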