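{
 "table4_overlap_operator.tsv": "72d7417d05f3dd8778e1833c830e840b7e676feb773b83966522ff6121489653",
 "table5_overlap_ample.tsv": "362db03090ef2577b96804c49a8e589bafedf5b95772a78f944b8460162b4fae",
 "table6_com_operator.tsv": "0b1c19730175a13c67c85418fe5318c0659b70076c172fe342939d2e5aa5d3c4",
 "table8_ecs_operator.tsv": "885452c2153c4dc2a08f3f35fb96eb56824463dfff1176e29b6e9277e0e90060",
 "table9_ecs_ample.tsv": "72b64e8074e057cd0261f5f87342dba28383e67683829bdb4d4b1dec7cef8eaa"
}
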