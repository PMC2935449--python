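{
  "26S proteasome": "26S proteasome",
  "SAGA subunits": "SAGA",
  "Ucp6": "Ubp2-Ucp6",
  "Nxt3": "Ubp3-Nxt3",
  "Sfp47": "Ubp4-Sfp47",
  "Ftp105": "Ubp5-Ftp105",
  "Bun62": "Ubp9-Bun62-Bun107",
  "Bun107": "Ubp9-Bun62-Bun107",
  "Tom70": "Ubp11-Tom70",
  "Cdc48": "Otu1-Cdc48"
}
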