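{
  "comment": "Default five-region scheme for the US wheat belt and state adjacency restricted to the states listed here. Both maps are overridable at load time.",
  "state_region": {
    "ND": "Northern",
    "SD": "Northern",
    "MN": "Northern",
    "MT": "Northern",
    "CA": "Pacific",
    "AZ": "Pacific",
    "WA": "PacificNorthwest",
    "OR": "PacificNorthwest",
    "ID": "PacificNorthwest",
    "UT": "PacificNorthwest",
    "KS": "GreatPlains",
    "NE": "GreatPlains",
    "TX": "GreatPlains",
    "OK": "GreatPlains",
    "CO": "GreatPlains",
    "OH": "Eastern",
    "IN": "Eastern",
    "NY": "Eastern",
    "SC": "Eastern",
    "MO": "Eastern",
    "VA": "Eastern",
    "NC": "Eastern",
    "GA": "Eastern",
    "IL": "Eastern",
    "MI": "Eastern"
  },
  "adjacency": {
    "ND": ["SD", "MN", "MT"],
    "SD": ["ND", "MN", "MT", "NE"],
    "MN": ["ND", "SD"],
    "MT": ["ND", "SD", "ID"],
    "CA": ["OR", "AZ"],
    "AZ": ["CA", "UT", "CO"],
    "WA": ["OR", "ID"],
    "OR": ["WA", "ID", "CA"],
    "ID": ["WA", "OR", "MT", "UT"],
    "UT": ["ID", "AZ", "CO"],
    "KS": ["NE", "MO", "OK", "CO"],
    "NE": ["SD", "KS", "MO", "CO"],
    "TX": ["OK"],
    "OK": ["KS", "TX", "MO", "CO"],
    "CO": ["KS", "NE", "OK", "UT", "AZ"],
    "OH": ["IN", "MI"],
    "IN": ["OH", "MI", "IL"],
    "NY": [],
    "SC": ["NC", "GA"],
    "MO": ["KS", "NE", "OK", "IL"],
    "VA": ["NC"],
    "NC": ["SC", "VA", "GA"],
    "GA": ["SC", "NC"],
    "IL": ["IN", "MO"],
    "MI": ["OH", "IN"]
  }
}
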