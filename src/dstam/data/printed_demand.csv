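label,covered_population
one_site_catchment,700472
second_site_additional_catchment,122665
two_site_catchment,823137
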