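process_type	total_average_number_of_processes
in_situ_speciation	17440.6
founder_event_speciation	8259.6
allopatry	14.3
subset_sympatry	42.96
dispersal	7090.9
extinction	11660.24
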