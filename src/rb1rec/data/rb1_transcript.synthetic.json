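{
 "gene_symbol": "RB1",
 "version": "synthetic (seed=2021)",
 "exons": [
  {
   "index": 1,
   "cdna_start": 1,
   "cdna_end": 257
  },
  {
   "index": 2,
   "cdna_start": 258,
   "cdna_end": 375
  },
  {
   "index": 3,
   "cdna_start": 376,
   "cdna_end": 480
  },
  {
   "index": 4,
   "cdna_start": 481,
   "cdna_end": 608
  },
  {
   "index": 5,
   "cdna_start": 609,
   "cdna_end": 721
  },
  {
   "index": 6,
   "cdna_start": 722,
   "cdna_end": 831
  },
  {
   "index": 7,
   "cdna_start": 832,
   "cdna_end": 936
  },
  {
   "index": 8,
   "cdna_start": 937,
   "cdna_end": 1031
  },
  {
   "index": 9,
   "cdna_start": 1032,
   "cdna_end": 1140
  },
  {
   "index": 10,
   "cdna_start": 1141,
   "cdna_end": 1250
  },
  {
   "index": 11,
   "cdna_start": 1251,
   "cdna_end": 1358
  },
  {
   "index": 12,
   "cdna_start": 1359,
   "cdna_end": 1438
  },
  {
   "index": 13,
   "cdna_start": 1439,
   "cdna_end": 1530
  },
  {
   "index": 14,
   "cdna_start": 1531,
   "cdna_end": 1621
  },
  {
   "index": 15,
   "cdna_start": 1622,
   "cdna_end": 1738
  },
  {
   "index": 16,
   "cdna_start": 1739,
   "cdna_end": 1841
  },
  {
   "index": 17,
   "cdna_start": 1842,
   "cdna_end": 1923
  },
  {
   "index": 18,
   "cdna_start": 1924,
   "cdna_end": 2017
  },
  {
   "index": 19,
   "cdna_start": 2018,
   "cdna_end": 2144
  },
  {
   "index": 20,
   "cdna_start": 2145,
   "cdna_end": 2259
  },
  {
   "index": 21,
   "cdna_start": 2260,
   "cdna_end": 2354
  },
  {
   "index": 22,
   "cdna_start": 2355,
   "cdna_end": 2480
  },
  {
   "index": 23,
   "cdna_start": 2481,
   "cdna_end": 2569
  },
  {
   "index": 24,
   "cdna_start": 2570,
   "cdna_end": 2694
  },
  {
   "index": 25,
   "cdna_start": 2695,
   "cdna_end": 2780
  },
  {
   "index": 26,
   "cdna_start": 2781,
   "cdna_end": 2863
  },
  {
   "index": 27,
   "cdna_start": 2864,
   "cdna_end": 3106
  }
 ],
 "cds_start_cdna": 140,
 "cds_end_cdna": 2926,
 "cds_sequence": "ATGCAAGAATTGGAGATTAGATACTCGTACTGGGCTCAAGGATACATGTTTAACCGCACTTTGACTCATCGTCAGCTCAGGGGAATCTACATTCGCGCTACGTTAATTGCCCTCCGTACCTCCGGTCCCCCACGAGCCAACGCAAGATCACACTGCGTTTCCCGAGAAGGCCTACTAAACCCATTACGTCCAGGTAGAAGTAGTCTCCCGTCTATGATCAGCCACCGGCCATACATGGTACTGAACGCAATTGGGTGTGCGTGTCCGCAGAACGTGTGTAAGCAGTGGCACAGGGAGCCAGTTCCTGCGGAACACCTGATGACTACCACGTTAAGAAGAACCGCAATCGCCGGTATTGTATCGGTCCCTAGAACGTGGTTACCCAGGAGCATGACCCGCACTTCCTATGCTGCGGCTCGCAAACTAATCCTAGTACTTTTGAAGAGCGGAAACCTTTTAACAAGGAAGCGTGTATGCGACTACACTCACCCGGCGGCGGGTCAGGCGCTGTCGATAATGGCGTACGGCCACATCGGAACATCGAGGCACAACCATGAATCATTGTTACCGAGTCTCTTCGGATATTTGGACATAGGGCATGTAGGCATTCATCAGCGGGAAACGCCTTTTTGCGCTCCGTCGATCCGGGTCCAAGCACACCAAGTACCATCAATATGTCCAAACTTTGAAATCGATTCTGTCTGTTCGTCGCTTCCCTGGCTCCTCCTGTGGCAAGTGATAATCTGCCAAAATCTTGCTGACCAGTTAGTAACACGTGCAGCAGCCCAGCGGCATGATAATCCTATCACACGGATTTATCTCATGCTTGCTCATGTGCTGCTAACACCTTCAAAGCCCGTGGGCAAGCTTTCCTGGTGTTGGGCACACGGTCAGCCCAGTCGCGAAGCGATATCTAGAGAATCTCGACCCAAAGCAGTCTGTGTGCTCCCTCCCTCCGCGCTAGACGGCGTAAACTGCGATAGGGCTGGACAATTTAACGCGCTACGATCCAGACGTGTCCATTCCTTGGGGCCTTTTCCTTCCCTTCTAACGAGTATGGAGCTTGGACGAAGCCTATGGTCCACAGTGAGACGACGCACAACGCAGCAAGCGCGCTATCAGGGTTTTTATATTAGTTACCGTTCTACTTATCGTCAATCACCGGTGTCTGCCTACGCCCGGAAGCTCTGGAGAAAGAATCTAGAATTGCATTCAGTTTTCAGATTGAATCGTGGAGGCCGTTGTCCGCAATGGACCAATCGCAATTCTTCACCCTCCCCAGTTATACTCCACGATCTACGCGAAGCAACTAGTTCCGTTAGTACTATTCCATCTTCTGGAGGACATACAGACATCGAGGATACCGCGCACCCAGGCAATCGACAAGGCGTCTGTGAGGCGTCTTTCGTTGAAAGACCCATAATGGAATCACTTCTTTCCACCCTACCCCGCCTAGCGTGCTGCCTTACGATCTATCTTCTCGCCTGCCGTTGTCGTGAGGTCGGATTCCGCTTGAAAAACTTGTGGGGTCCCTGCGGCTGCGATAGGTGCCGGCGGGCTGGGCCCAGTATGTGGTCTGCGAGATTAGGTAATATAGGAGATGTGGCTGTTAGATGCGATTATCTCAGACAGAGGAGACAGACTTGTGGAAGTATCCCAAGTGTCAGGAGATATTTTAATACCCCACAAGCGACTGACTCTCAGGATGATGAAGACTTCATGTCCCTGCTTTACGTGCACATAAGCTTTCCCGGCCCGGAGAACGATCGGCCTGGTGTTGCACCTTGCGAGGTCAAAGGAAGACCTAAAAGCATAAAGCCCCGAGACACAGGCGGGTCCATCAACAGGATCGGTTTACGCGATTTAGCCGTTTCTCGGGATCAACCAAGAGAGCACTACCGCGACCCGCAGAGGATTGGGTCTACAGGTCAAAGTGGAAATCATGAGATTCGCGTAGGGGGAGTATACAAGACAGGTTTAGGCTATGGCCACGGAACCTGTCCATTCGTATCCAACAGTTTACTTTGTACGTCTCGGATCAAATCCAGGAACGGTGCTTCCAGCGAATCATACACGCGAAGGGTTCGTGTGCCCATCTTGGACGCGGCTTCCTCAGCAGTCGTCACCCAACCTCATATGCTATCCGGCGATTGGAGAACGACTCGAGTACCCAAGTACACAAGCCACTTGGGGAGACTTTGGATTTCGATGAGAGACGTTAACCGGGAAGTGGCCCCCAGGTCCTACCCCGCAATGCTGGTTGCACTATCGTTAGCCACGAAGTCGATCTTTTATACTCTTAGCGCCCCGCCGAAGGACACGCAGGTGAGTGTCGGGTATAGAGATCATCGCCTGCCTGATGGTATCGGGGGTGCATTCTATCGAAGCCAACGCTCCGTAGTAAGTATGTCACTACGCCAATGGGACCAGCAATGGGAAATGCGGCTTTCTCAGCGCAGCAGCGATGCAACCCCCCCTGGTATTTGGGAAGTTCACAACAAACGTAAACAGTTTCTAAAACTGTTGAACGTCGAGATCGCGGAACCCGCATACTCTAAAGAAAGTCAGAAGGAACCCCCCCTCGTCATGGGAAATAACTTCGTATCCCGCCATACCATTGTATCGTACATCTGGCTGAGGACTGGTAAGACAATTTGCCGCATAGTTAGTAACTTGTTCACCGAGGGGGTAGAGCGGAAACTCTATATTCGGATCATCGTTCGAATACCGTACAAAAACTCGGAGCTGGTCTACCTACCACCCAAAGAACGCCGCCCCTACTTTTAA",
 "promoter_note": "",
 "note": "SYNTHETIC stand-in for an RB1 transcript model: 27 exons, 928-aa protein, 2787-nt CDS match the gene's published anchors, but exon boundaries and the CDS sequence are generated. Replace with a curated RefSeq-derived config (record the transcript version here) before interpreting real variants."
}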