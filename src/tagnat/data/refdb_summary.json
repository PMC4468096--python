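{
  "n_genes_total": 19346,
  "n_genes_with_catg": 18940,
  "n_tags_total": 173207,
  "n_tags_unambiguous": 169843
}
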