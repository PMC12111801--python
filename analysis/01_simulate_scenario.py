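#!/usr/bin/env python
"""Generate the default synthetic scenario used by the downstream drivers.

Writes every pipeline input dialect (SMILES inventory, prediction table,
docking scores, contact table with alignment, GMT) under results/scenario/.
The planted ground truth (hot targets, permeability classes, strong ligand
class, fingerprint columns, enriched pathway) is recorded alongside so later
drivers can score recovery.
"""

from click.testing import CliRunner

from metafunnel.cli import main

OUT = "results/scenario"

if __name__ == "__main__":
    result = CliRunner().invoke(main, ["simulate", "--out", OUT, "--seed", "1"])
    if result.exit_code != 0:
        raise SystemExit(result.output or result.exit_code)
    print(f"synthetic scenario written to {OUT}/ (seed 1, 500 metabolites)")
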