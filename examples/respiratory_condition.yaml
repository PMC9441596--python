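# Fully respiratory reference state: growth pinned at a rate where protein
# availability is non-limiting.
name: respiratory_reference
growth_rate: 0.2
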