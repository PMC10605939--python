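{
  "carriers.tsv": "e2686c40becd1dfb567725bbbf26e93e449b413f8b63f1ffd76bf4c0728c41cb",
  "families.tsv": "87da1c92e9f609955e09ae293eb4f3bd76dd0c4c30e88f9cc4c3c816d66e52aa",
  "table1_lesions.tsv": "459fef456072c5a1fa0d8b0f1d5ac00176a2290796324f2a32b665cfadea0907",
  "table2_evidence.tsv": "7a965d4f2d906e1c2847361cb10f4ddc8ac6f6445653e811f039fd67fc21745f",
  "table3_tumors.tsv": "7975ecbd939bf08af23ab91a9327fe635c8908d4d6502679aa3098a4186f001b",
  "table4_crypt_screens.tsv": "2d225782038caf8c176d48997358143dca0922b7d56b5c99a2bf0513f4d16a67",
  "variants.tsv": "5b99d37ee869ea535d84f7066533b6da41ef438d4bbeaf6ae7ab9bc59f699499"
}
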