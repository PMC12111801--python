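"""Packaged reference tables transcribed from the printed study results.

These small fixtures make the desk-reproducible statistics runnable offline:
the brain-permeant docking hit heat-map with its per-receptor 95th-percentile
affinity limits, the natural-metabolite/indole docking panel with class
labels, the reference-drug scores, the consensus residue tables for the
PPAR and RXR panels, and the gene set selected by both prediction models.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .docking import DockingMatrix

_RECEPTORS = ["PPARA", "PPARB", "PPARG", "RXRA", "RXRB", "RXRG"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("metafunnel.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_bbb_hit_table(block: str | None = None) -> pd.DataFrame:
    """Brain-permeant ligands scoring above the 95th affinity percentile
    (wide score table; ``block`` selects the database- or literature-derived
    inventory)."""
    df = _read("table1_bbb_hits.tsv")
    if block is not None:
        df = df[df["block"] == block].reset_index(drop=True)
    return df


def load_percentile_limits(block: str) -> dict[str, float]:
    """Printed per-receptor 95th-percentile affinity limits."""
    df = _read("table1_limits.tsv")
    df = df[df["block"] == block]
    return dict(zip(df["receptor"], df["limit"]))


def load_metabolite_panel() -> tuple[DockingMatrix, set[str]]:
    """Natural-metabolite and indole docking panel with class labels.

    Returns the score matrix plus the set of brain-permeant ligand ids.
    """
    df = _read("table2_metabolite_panel.tsv")
    scores = df.set_index("ligand_id")[_RECEPTORS]
    classes = dict(zip(df["ligand_id"], df["class"]))
    bbb = set(df.loc[df["bbb"].astype(bool), "ligand_id"])
    return DockingMatrix(scores=scores, ligand_class=classes), bbb


def load_reference_drugs() -> pd.DataFrame:
    """Reference agonist/antagonist docking scores (long form)."""
    return _read("table3_reference_drugs.tsv")


def load_shared_targets() -> list[str]:
    """Gene symbols selected by both prediction models."""
    text = resources.files("metafunnel.data").joinpath("shared_targets.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]
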