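{
  "Ubp1": [],
  "Ubp2": ["Ucp6"],
  "Ubp3": ["Nxt3"],
  "Ubp4": ["Sfp47"],
  "Ubp5": ["Ftp105"],
  "Ubp6": ["26S proteasome"],
  "Ubp7": [],
  "Ubp8": ["Sus1", "Tra1", "Sgf73", "Sgf29"],
  "Ubp9": ["Bun62", "Bun107"],
  "Ubp11": ["Tom70"],
  "Ubp12": [],
  "Ubp14": [],
  "Ubp15": [],
  "Ubp16": [],
  "Uch1": [],
  "Uch2": ["26S proteasome"],
  "Otu1": ["Cdc48"],
  "Otu2": [],
  "Sst2": [],
  "Rpn11": ["26S proteasome"]
}
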