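# EXAMPLE relative-risk weight table.  These numbers are illustrative
# placeholders, not vetted epidemiological estimates: edit them to the
# relative-risk values appropriate for your study before use.
diabetes: 1.46
hypertension: 1.61
smoking: 1.59
depression: 1.65
low_education: 1.59
obesity: 1.60
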