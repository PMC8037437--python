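{
 "note": "SYNTHETIC/approximate pRB segmentation (RB-N, pocket A, pocket-loop, pocket B, RB-C with intervening linkers). Residue boundaries are approximate; transcribe a curated map (e.g. from the Dick & Rubin domain description) for real analyses. RB-C is labelled structured here; the kind labels are data and may be edited.",
 "protein_length": 928,
 "segments": [
  {
   "name": "N-terminal-linker",
   "aa_start": 1,
   "aa_end": 52,
   "kind": "linker"
  },
  {
   "name": "RB-N",
   "aa_start": 53,
   "aa_end": 355,
   "kind": "structured"
  },
  {
   "name": "linker-N-A",
   "aa_start": 356,
   "aa_end": 379,
   "kind": "linker"
  },
  {
   "name": "pocket-A",
   "aa_start": 380,
   "aa_end": 577,
   "kind": "structured"
  },
  {
   "name": "pocket-loop",
   "aa_start": 578,
   "aa_end": 644,
   "kind": "linker"
  },
  {
   "name": "pocket-B",
   "aa_start": 645,
   "aa_end": 787,
   "kind": "structured"
  },
  {
   "name": "linker-B-C",
   "aa_start": 788,
   "aa_end": 828,
   "kind": "linker"
  },
  {
   "name": "RB-C",
   "aa_start": 829,
   "aa_end": 928,
   "kind": "structured"
  }
 ]
}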