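# Unit weight table: composite score = count of present factors.
diabetes: 1.0
hypertension: 1.0
smoking: 1.0
depression: 1.0
low_education: 1.0
obesity: 1.0
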