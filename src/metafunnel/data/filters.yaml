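# Size rules applied before any downstream analysis.
min_heavy_atoms: 5        # "four atoms or fewer" are discriminated
max_smiles_length: 200    # characters of the canonical SMILES
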