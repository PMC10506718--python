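{
  "comment": "Reference cysteine arrays. Spacer ranges are inclusive (min,max) residue counts between consecutive cysteines, derived from the curated seed alignments (observed inter-cysteine gaps with +/-2 slack, floored at 0). Connectivity pairs are putative disulfides (1-based cysteine indices); matching never uses them.",
  "motifs": [
    {
      "name": "Diapausin",
      "n_cys": 6,
      "spacers": [[5, 9], [3, 7], [7, 11], [4, 8], [10, 14]],
      "connectivity": [[1, 4], [2, 5], [3, 6]]
    },
    {
      "name": "MND",
      "n_cys": 8,
      "spacers": [[4, 8], [2, 6], [10, 14], [5, 9], [3, 7], [1, 5], [0, 4]],
      "connectivity": [[1, 5], [2, 6], [3, 7], [4, 8]]
    },
    {
      "name": "TID",
      "n_cys": 6,
      "spacers": [[5, 9], [1, 5], [15, 19], [4, 8], [0, 3]],
      "connectivity": [[1, 4], [2, 5], [3, 6]]
    },
    {
      "name": "Macin",
      "n_cys": 10,
      "spacers": [[3, 7], [2, 6], [5, 9], [4, 8], [2, 6], [3, 7], [0, 4], [4, 8], [0, 3]],
      "connectivity": [[1, 6], [2, 7], [3, 8], [4, 9], [5, 10]]
    },
    {
      "name": "Drosomycin",
      "n_cys": 8,
      "spacers": [[0, 3], [6, 10], [2, 6], [7, 11], [3, 7], [0, 3], [2, 6]],
      "connectivity": [[1, 8], [2, 5], [3, 6], [4, 7]]
    },
    {
      "name": "MND_6Cys",
      "n_cys": 6,
      "spacers": [[10, 14], [2, 6], [4, 8], [9, 13], [0, 4]],
      "connectivity": [[1, 5], [2, 4], [3, 6]]
    },
    {
      "name": "SaposinB",
      "n_cys": 6,
      "spacers": [[6, 10], [9, 13], [4, 8], [9, 13], [6, 10]],
      "connectivity": [[1, 6], [2, 5], [3, 4]]
    }
  ]
}
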