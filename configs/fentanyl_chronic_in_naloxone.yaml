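# Example scenario: medium fentanyl overdose in chronic opioid users,
# rescued by a single 4 mg IN naloxone dose (reduced 200-subject run).
opioid: fentanyl
dose_mg: 1.63
population: chronic
antagonist: naloxone
route: intranasal
n_doses: 1
seed: 1
n_subjects: 200
bootstrap_m: 100
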