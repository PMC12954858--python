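{
  "version": 1,
  "comment": "Space-group generator table. Rotations are integer matrices acting on fractional coordinates (x' = R x + t); translations are given in 24ths of a cell edge. The full operator list is obtained by closure at load time and verified to form a group. 'ambiguity' is an integer reindexing matrix acting on Miller indices (row convention, h' = h M) describing the merohedral indexing ambiguity, where one exists.",
  "groups": {
    "P1": {
      "number": 1,
      "generators": [],
      "ambiguity": null
    },
    "P21": {
      "number": 4,
      "aliases": ["P1211", "P 1 21 1", "P 21"],
      "generators": [
        {"rot": [[-1, 0, 0], [0, 1, 0], [0, 0, -1]], "trans24": [0, 12, 0]}
      ],
      "ambiguity": null
    },
    "P21212": {
      "number": 18,
      "aliases": ["P 21 21 2"],
      "generators": [
        {"rot": [[-1, 0, 0], [0, -1, 0], [0, 0, 1]], "trans24": [0, 0, 0]},
        {"rot": [[-1, 0, 0], [0, 1, 0], [0, 0, -1]], "trans24": [12, 12, 0]}
      ],
      "ambiguity": null
    },
    "I222": {
      "number": 23,
      "aliases": ["I 2 2 2"],
      "generators": [
        {"rot": [[-1, 0, 0], [0, -1, 0], [0, 0, 1]], "trans24": [0, 0, 0]},
        {"rot": [[1, 0, 0], [0, -1, 0], [0, 0, -1]], "trans24": [0, 0, 0]},
        {"rot": [[1, 0, 0], [0, 1, 0], [0, 0, 1]], "trans24": [12, 12, 12]}
      ],
      "ambiguity": null
    },
    "P3221": {
      "number": 154,
      "aliases": ["P 32 2 1"],
      "generators": [
        {"rot": [[0, -1, 0], [1, -1, 0], [0, 0, 1]], "trans24": [0, 0, 16]},
        {"rot": [[0, 1, 0], [1, 0, 0], [0, 0, -1]], "trans24": [0, 0, 0]}
      ],
      "ambiguity": [[-1, 0, 0], [0, -1, 0], [0, 0, 1]]
    },
    "P6122": {
      "number": 178,
      "aliases": ["P 61 2 2"],
      "generators": [
        {"rot": [[1, -1, 0], [1, 0, 0], [0, 0, 1]], "trans24": [0, 0, 4]},
        {"rot": [[0, 1, 0], [1, 0, 0], [0, 0, -1]], "trans24": [0, 0, 8]}
      ],
      "ambiguity": null
    }
  }
}
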