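{
  "table1.tsv": "4df1f4e24022119d365fb61adac4b56053d96deb7e1b75bb221c59710c1dabe4",
  "table2.tsv": "74ea19fcf07ad8fc63613bc0f7ffe9ea3dd31d29f5385a778d2e183f0eb32032",
  "table3.tsv": "bb37ecdfbc3d34a4d1fd6f347b349365c3d0257b0b32149e3452ae17f35d4a3b"
}
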