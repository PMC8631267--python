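{
  "features": {
    "color": {"values": ["red", "yellow", "blue"], "kind": "categorical"},
    "shape": {"values": ["circle", "square", "diamond"], "kind": "categorical"}
  },
  "anchor": {
    "agent": {"color": "red", "shape": "square"},
    "recipient": {"color": "yellow", "shape": "circle"}
  },
  "conditions": {
    "A1": {"result": ["r", "a"], "gloss": "recipient takes the agent's shape"},
    "A2": {"result": ["r", "n"], "gloss": "recipient takes a brand-new shape"},
    "A3": {"result": ["a", "r"], "gloss": "recipient takes the agent's color"},
    "A4": {"result": ["n", "r"], "gloss": "recipient takes a brand-new color"},
    "A5": {"result": ["a", "a"], "gloss": "recipient takes the agent's color and shape"},
    "A6": {"result": ["n", "n"], "gloss": "recipient takes a brand-new color and shape"}
  },
  "task_grid": [
    {"agent": ["a", "a"], "recipient": ["n", "r"]},
    {"agent": ["a", "a"], "recipient": ["r", "n"]},
    {"agent": ["a", "a"], "recipient": ["n", "n"]},
    {"agent": ["n", "a"], "recipient": ["r", "r"]},
    {"agent": ["n", "a"], "recipient": ["n", "r"]},
    {"agent": ["n", "a"], "recipient": ["r", "n"]},
    {"agent": ["n", "a"], "recipient": ["n", "n"]},
    {"agent": ["a", "n"], "recipient": ["r", "r"]},
    {"agent": ["a", "n"], "recipient": ["n", "r"]},
    {"agent": ["a", "n"], "recipient": ["r", "n"]},
    {"agent": ["a", "n"], "recipient": ["n", "n"]},
    {"agent": ["n", "n"], "recipient": ["r", "r"]},
    {"agent": ["n", "n"], "recipient": ["n", "r"]},
    {"agent": ["n", "n"], "recipient": ["r", "n"]},
    {"agent": ["n", "n"], "recipient": ["n", "n"]}
  ],
  "counterbalance_pairs": [[0, 1], [4, 5], [8, 9], [12, 13]],
  "counterbalance_blocks": [[3, 7], [4, 8], [5, 9], [6, 10]],
  "menu": "full"
}
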