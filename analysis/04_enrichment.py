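#!/usr/bin/env python
"""Pathway over-representation of the selected targets.

Tests the selected synthetic target set against the generated GMT with the
one-sided hypergeometric test, BH-FDR and strength, and reports whether the
planted pathway tops the list. Writes results/enrichment.tsv (volcano-ready
columns: discovery_rate vs strength).
"""

from dataclasses import asdict
from pathlib import Path

import pandas as pd

from metafunnel import enrichment, io

SCENARIO = Path("results/scenario")

if __name__ == "__main__":
    selected = set(
        pd.read_csv("results/frequency_table.tsv", sep="\t")
        .query("selected")["gene"]
    )
    annotation = io.read_gmt(SCENARIO / "pathways.gmt")
    universe = {l.strip() for l in (SCENARIO / "universe.txt").read_text().splitlines() if l.strip()}
    results = enrichment.run_enrichment(selected, annotation, universe | selected)
    df = pd.DataFrame([asdict(r) for r in results])
    df.to_csv("results/enrichment.tsv", sep="\t", index=False)
    top = results[0]
    print(f"top pathway: {top.pathway_id} ({top.pathway_name}), "
          f"k/K = {top.k}/{top.K}, FDR = {top.fdr:.3g}, strength = {top.strength:.2f}")
    print(f"{sum(r.significant for r in results)}/{len(results)} pathways at FDR <= 0.05")
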