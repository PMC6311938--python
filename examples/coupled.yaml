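# A small synthetic universe with two planted coupled disease pairs:
# each pair shares 6 eQTL RNAs in one tissue and has a planted
# conditional comorbidity odds ratio of 3.
n_diseases: 20
n_snps: 120
n_rnas: 400
n_tissues: 2
n_patients: 4000
planted_pairs:
  - {disease_i: 0, disease_j: 1, shared_rna_count: 6, comorbidity_log_odds: 1.0986122886681098}
  - {disease_i: 2, disease_j: 3, shared_rna_count: 6, comorbidity_log_odds: 1.0986122886681098}
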