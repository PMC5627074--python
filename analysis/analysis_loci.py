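"""Reference CpG sets of the simulated amplicon loci (shared by steps 05/06)."""

LOCI = {
    "qnfc1_like": {"cpg_positions": [50]},
    "cabin1_like": {"cpg_positions": [10, 35, 60, 85]},
    "nadrin2_like": {"cpg_positions": [12, 30, 48]},
}
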