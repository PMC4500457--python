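{
  "taxon": "Neotropical freshwater Siluriformes",
  "n_species": 595,
  "n_articles": 402,
  "n_authors": 252,
  "n_journals": 43,
  "window_start": 1990,
  "window_end": 2014,
  "pre_window_species": 1452,
  "pre_window_start": 1758,
  "family_counts": {
    "Loricariidae": 285,
    "Trichomycteridae": 129,
    "Nematogenyidae": 0
  }
}
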