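"""Seeded synthetic inputs with planted ground truth for every funnel stage.

Each generator emulates the shape of one upstream data source the pipeline
consumes: a metabolite inventory with SMILES, a target-prediction export, a
ligand x receptor docking-score grid, a residue-contact table with a
multiple-sequence alignment, and a GMT pathway annotation. Ground truth
(planted hot targets, permeability classes, strong-affinity ligand class,
fingerprint columns, enriched pathway) is known by construction, so recovery
by the analysis modules is testable end to end without any downloads.

All generators are deterministic given (seed, config): a single root seed is
expanded into per-stage substreams keyed by a stable hash of the stage name,
so adding a stage never perturbs earlier streams.
"""

from __future__ import annotations

import itertools
import warnings
import zlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import chem
from .chem import EllipseParams, MetaboliteRecord
from .docking import DockingMatrix
from .enrichment import PathwayAnnotation
from .fingerprint import AA_3TO1, ConsensusMap, ResidueContact, categorize_residue, consensus_map_from_alignment
from .targets import TargetPrediction

import pandas as pd

HOT_TARGETS_DEFAULT = (
    "PPARA", "PPARD", "PPARG", "RXRA", "RXRB", "RXRG",
    "NR1H4", "FABP3", "CHRNA7", "PTGER2",
)

RECEPTORS_DEFAULT = ("PPARA", "PPARB", "PPARG", "RXRA", "RXRB", "RXRG")


@dataclass
class SyntheticConfig:
    """Scenario parameters; the defaults are the study conditions."""

    seed: int = 0
    n_metabolites: int = 500
    # permeability class mix emulating the reported funnel (~56% GI-absorbed,
    # ~17% of those brain-permeant)
    frac_bbb: float = 0.10
    frac_gi_only: float = 0.46
    include_small: int = 0  # extra sub-threshold molecules (filter fodder)
    # target fishing
    hot_targets: tuple[str, ...] = HOT_TARGETS_DEFAULT
    n_background_genes: int = 190
    f_hot: float = 0.6
    f_bg: float = 0.1
    # docking
    receptors: tuple[str, ...] = RECEPTORS_DEFAULT
    score_mean_screen: float = -5.0
    score_mean_planted: float = -8.0
    score_sigma: float = 1.0
    planted_class: str = "indole"
    n_planted_ligands: int = 50
    score_bounds: tuple[float, float] = (-12.0, 0.0)
    screen_bbb_fraction: float = 0.2  # permeant fraction among screen ligands
    # fingerprint
    consensus_length: int = 60
    n_planted_columns: int = 8
    contact_probability: float = 1.0
    noise_contact_rate: float = 0.02
    # enrichment
    n_pathways: int = 50
    planted_pathway_size: int = 15
    planted_overlap: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.f_bg < self.f_hot <= 1):
            raise ValueError("need 0 <= f_bg < f_hot <= 1")
        if self.score_sigma <= 0:
            raise ValueError("score sigma must be positive")
        for p in (self.contact_probability, self.noise_contact_rate,
                  self.frac_bbb, self.frac_gi_only):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def gene_universe(self) -> list[str]:
        return list(self.hot_targets) + [
            f"G{i:04d}" for i in range(1, self.n_background_genes + 1)
        ]


def substream(seed: int, stage: str) -> np.random.Generator:
    """Per-stage RNG derived from the root seed and a stable name hash."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# Fragment-based metabolite generation
# ---------------------------------------------------------------------------


def _candidate_smiles() -> list[str]:
    """Chemically valid SMILES assembled from a small fragment vocabulary
    (alkyl chains, benzene, indole, hydroxyl, amine, carboxyl, amide)."""
    chains = ["C" * i for i in range(0, 10)]
    tails = ["", "O", "N", "C(=O)O", "C(=O)N", "C(=O)C"]
    out: list[str] = []
    for ch, tail in itertools.product(chains, tails):
        if ch or tail:
            out.append(ch + tail)
        # branched variant
        if len(ch) >= 2:
            out.append(f"CC({tail or 'C'}){ch}")
    aromatics = ["c1ccccc1", "Oc1ccccc1", "Nc1ccccc1", "c1cc(O)ccc1"]
    for ar, ch, tail in itertools.product(aromatics, chains[:8], tails):
        out.append(ar + ch + tail)
    for ch, tail in itertools.product(chains[:7], tails):
        out.append(f"c1ccc2c(c1)c({ch}{tail})c[nH]2")  # 3-substituted indole
    # polyols and polyacids (high-TPSA region)
    for k, j in itertools.product(range(1, 7), range(0, 5)):
        out.append("OC" + "C(O)" * k + "C" * j + "CO")
        out.append("OC(=O)" + "C" * j + "C(O)" * k + "C(=O)O")
        out.append("NC(=O)" + "C(O)" * k + "C" * j + "C(=O)N")
    # di-acids, amide-acids and amino acids (moderately polar: absorbed but
    # typically outside the brain-permeation region)
    for i, j in itertools.product(range(0, 6), range(0, 6)):
        out.append(f"OC(=O){'C' * i}C(O){'C' * j}C(=O)O")
        out.append(f"NC(=O){'C' * i}C(O){'C' * j}C(=O)O")
        out.append(f"OC(=O){'C' * i}C(N){'C' * j}C(=O)O")
    for i in range(0, 8):
        out.append(f"OC(=O){'C' * i}C(=O)O")
        out.append(f"NC(=O){'C' * i}C(=O)O")
        out.append(f"NC(=O){'C' * i}C(=O)N")
        out.append(f"NC({'C' * i})C(=O)O")
        out.append(f"NC({'C' * i}c1ccccc1)C(=O)O")
        out.append(f"OC(=O)C({'C' * i})c1ccc(O)cc1C(=O)O")
    for i, j in itertools.product(range(0, 6), range(0, 6)):
        out.append(f"OC(=O){'C' * i}C(O)C(O){'C' * j}C(=O)O")
        out.append(f"NC(=O){'C' * i}C(O){'C' * j}C(=O)N")
        out.append(f"OC{'C' * i}C(O){'C' * j}C(=O)O")
    for k in range(1, 6):
        out.append("CC(=O)N" + "CC(=O)N" * k + "CC(=O)O")  # peptide-like
    for i in range(0, 8):
        out.append(f"NC(=O)c1ccccc1{'C' * i}C(=O)O")
        out.append(f"OC(=O){'C' * i}c1ccc(C(=O)O)cc1")
        out.append(f"O=S(=O)(N){'C' * i}C(=O)O")
        out.append(f"O=S(=O)(N){'C' * i}c1ccccc1")
    for i, j in itertools.product(range(0, 5), range(0, 5)):
        out.append(f"OC(=O){'C' * i}S{'C' * j}C(=O)O")
    # pure hydrocarbons (zero TPSA: outside the absorption ellipse)
    out += ["C" * n for n in range(5, 22)]
    out += [f"CC(C){'C' * n}" for n in range(2, 16)]
    out += [f"CC(CC){'C' * n}C" for n in range(2, 14)]
    out += ["c1ccccc1" + "C" * n for n in range(0, 16)]
    out += [f"{'C' * i}c1ccccc1{'C' * j}"
            for i in range(1, 9) for j in range(1, 9)]
    out += ["c1ccc2ccccc2c1" + "C" * n for n in range(0, 10)]
    out += [f"{'C' * i}c1ccc2ccccc2c1" for i in range(1, 9)]
    out += [f"C=C{'C' * n}" for n in range(3, 19)]
    out += [f"CC=C{'C' * n}C=CC" for n in range(1, 13)]
    out += ["C1CCCCC1" + "C" * n for n in range(0, 13)]
    out += [f"CC(C)({'C' * i}C)C{'C' * j}" for i in range(1, 7) for j in range(1, 7)]
    return out


@lru_cache(maxsize=1)
def _library() -> dict[str, list[MetaboliteRecord]]:
    """Descriptor-annotated fragment library partitioned by permeability class."""
    ellipses = chem.load_ellipses()
    gi, bbb = ellipses["gi"], ellipses["bbb"]
    pools: dict[str, list[MetaboliteRecord]] = {"bbb": [], "gi_only": [], "outside": []}
    seen: set[str] = set()
    for smi in _candidate_smiles():
        try:
            rec = chem.parse_and_canonicalize(smi)
        except chem.SmilesParseError:
            continue
        if rec.canonical_smiles in seen or rec.heavy_atom_count < 5:
            continue
        seen.add(rec.canonical_smiles)
        rec = chem.compute_descriptors(rec)
        if gi.contains(rec.tpsa, rec.wlogp):
            key = "bbb" if bbb.contains(rec.tpsa, rec.wlogp) else "gi_only"
        else:
            key = "outside"
        pools[key].append(rec)
    return pools


def gen_metabolites(
    config: SyntheticConfig,
) -> tuple[list[MetaboliteRecord], dict[str, str]]:
    """Metabolite inventory with planted permeability classes.

    Returns descriptor-annotated records plus the planted class per id
    ("bbb", "gi_only" or "outside"). Molecules are drawn without replacement
    from the class-matched fragment-library pool; an exhausted pool falls
    back to reuse with a warning (nearest achievable).
    """
    rng = substream(config.seed, "metabolites")
    pools = {k: list(v) for k, v in _library().items()}
    n = config.n_metabolites
    n_bbb = int(round(config.frac_bbb * n))
    n_gi = int(round(config.frac_gi_only * n))
    plan = (["bbb"] * n_bbb + ["gi_only"] * n_gi + ["outside"] * (n - n_bbb - n_gi))
    records: list[MetaboliteRecord] = []
    classes: dict[str, str] = {}
    cursors = {k: rng.permutation(len(v)).tolist() for k, v in pools.items()}
    for i, cls in enumerate(plan):
        pool, order = pools[cls], cursors[cls]
        if not order:
            warnings.warn(f"pool {cls!r} exhausted; reusing molecules")
            order.extend(rng.permutation(len(pool)).tolist())
        base = pool[order.pop()]
        mid = f"m{i + 1:04d}"
        records.append(
            MetaboliteRecord(
                id=mid, smiles=base.smiles, canonical_smiles=base.canonical_smiles,
                heavy_atom_count=base.heavy_atom_count,
                smiles_length=base.smiles_length,
                wlogp=base.wlogp, tpsa=base.tpsa, source="synthetic",
            )
        )
        classes[mid] = cls
    small = ["CCO", "CC=O", "C(=O)O", "CO", "CCN"]
    for j in range(config.include_small):
        smi = small[j % len(small)]
        rec = chem.compute_descriptors(chem.parse_and_canonicalize(smi))
        mid = f"s{j + 1:03d}"
        records.append(
            MetaboliteRecord(
                id=mid, smiles=smi, canonical_smiles=rec.canonical_smiles,
                heavy_atom_count=rec.heavy_atom_count,
                smiles_length=rec.smiles_length,
                wlogp=rec.wlogp, tpsa=rec.tpsa, source="synthetic",
            )
        )
        classes[mid] = "small"
    return records, classes


def gen_target_predictions(
    config: SyntheticConfig, metabolite_ids: list[str]
) -> list[TargetPrediction]:
    """Bernoulli prediction table: each metabolite hits each hot target with
    probability ``f_hot`` and each background gene with ``f_bg``."""
    rng = substream(config.seed, "target_predictions")
    genes = config.gene_universe
    hot = set(config.hot_targets)
    preds: list[TargetPrediction] = []
    hits = rng.random((len(metabolite_ids), len(genes)))
    for i, mid in enumerate(metabolite_ids):
        for j, gene in enumerate(genes):
            p = config.f_hot if gene in hot else config.f_bg
            if hits[i, j] < p:
                preds.append(TargetPrediction(metabolite_id=mid, gene_symbol=gene))
    return preds


def gen_docking_matrix(
    config: SyntheticConfig, ligand_classes: dict[str, str] | None = None
) -> tuple[DockingMatrix, dict[str, str]]:
    """Score grid with a planted strong-affinity class.

    Scores are Normal(mu_class, sigma) truncated to ``score_bounds``; the
    planted class mean sits ``score_mean_planted`` (stronger) against the
    screen background. When ``ligand_classes`` is not given, a panel of
    ``n_metabolites`` screen ligands plus ``n_planted_ligands`` planted-class
    ligands is synthesized.
    """
    rng = substream(config.seed, "docking")
    if ligand_classes is None:
        ligand_classes = {
            f"L{i + 1:04d}": "screen" for i in range(config.n_metabolites)
        }
        ligand_classes.update(
            {f"P{i + 1:03d}": config.planted_class
             for i in range(config.n_planted_ligands)}
        )
    ligands = list(ligand_classes)
    lo, hi = config.score_bounds
    grid = np.empty((len(ligands), len(config.receptors)))
    for i, lig in enumerate(ligands):
        mu = (config.score_mean_planted
              if ligand_classes[lig] == config.planted_class
              else config.score_mean_screen)
        grid[i] = np.clip(rng.normal(mu, config.score_sigma, len(config.receptors)),
                          lo, hi)
    scores = pd.DataFrame(grid, index=ligands, columns=list(config.receptors))
    return DockingMatrix(scores=scores, ligand_class=dict(ligand_classes)), dict(ligand_classes)


def gen_bbb_flags(config: SyntheticConfig, ligand_classes: dict[str, str]) -> set[str]:
    """Brain-permeant ligand ids: the planted class entirely, plus a
    ``screen_bbb_fraction`` Bernoulli sample of the screen background."""
    rng = substream(config.seed, "bbb_flags")
    permeable: set[str] = set()
    for lig, cls in ligand_classes.items():
        if cls == config.planted_class or rng.random() < config.screen_bbb_fraction:
            permeable.add(lig)
    return permeable


# ---------------------------------------------------------------------------
# Contact tables with a planted consensus fingerprint
# ---------------------------------------------------------------------------

_RESIDUE_POOL = tuple(AA_3TO1)  # 20 standard residues


@dataclass
class ContactScenario:
    contacts: list[ResidueContact]
    alignment: dict[str, str]
    author_offsets: dict[str, int]
    consensus_map: ConsensusMap
    planted_columns: dict[str, set[int]]


def gen_contact_table(
    config: SyntheticConfig, ligand_classes: dict[str, str]
) -> ContactScenario:
    """Residue contacts with planted high-frequency consensus columns.

    Fabricates one sequence per receptor as a gapped slice of a common
    consensus (so consensus numbering is exercised for real), then lets every
    ligand of the planted class contact each planted (receptor, column) pair
    with ``contact_probability``, plus uniform noise contacts elsewhere.
    """
    rng = substream(config.seed, "contacts")
    L = config.consensus_length
    col_res = {col: _RESIDUE_POOL[rng.integers(len(_RESIDUE_POOL))]
               for col in range(1, L + 1)}
    alignment: dict[str, str] = {}
    offsets: dict[str, int] = {}
    for r, rec in enumerate(config.receptors):
        gap_cols = set(rng.choice(np.arange(1, L + 1), size=4, replace=False).tolist())
        seq = "".join(
            "-" if col in gap_cols else AA_3TO1[col_res[col]]
            for col in range(1, L + 1)
        )
        alignment[rec] = seq
        offsets[rec] = 200 + 10 * r
    cmap = consensus_map_from_alignment(alignment, offsets)
    common = set.intersection(
        *({col for _, col in cmap.maps[rec].items()} for rec in config.receptors)
    )
    planted_pool = sorted(common)
    idx = rng.choice(len(planted_pool), size=config.n_planted_columns, replace=False)
    planted = {planted_pool[i] for i in idx.tolist()}
    planted_by_receptor = {rec: set(planted) for rec in config.receptors}
    inverse = {rec: cmap.invert(rec) for rec in config.receptors}
    contacts: list[ResidueContact] = []
    planted_ligs = [l for l, c in ligand_classes.items()
                    if c == config.planted_class]
    for rec in config.receptors:
        inv = inverse[rec]
        for lig in planted_ligs:
            for col in sorted(planted):
                if rng.random() < config.contact_probability:
                    resname = col_res[col]
                    contacts.append(
                        ResidueContact(
                            ligand_id=lig, receptor_id=rec,
                            author_resnum=inv[col], residue_name=resname,
                            categories=frozenset({"any"} | categorize_residue(resname)),
                        )
                    )
            if config.noise_contact_rate > 0:
                for col in sorted(set(inv) - planted):
                    if rng.random() < config.noise_contact_rate:
                        resname = col_res[col]
                        contacts.append(
                            ResidueContact(
                                ligand_id=lig, receptor_id=rec,
                                author_resnum=inv[col], residue_name=resname,
                                categories=frozenset({"any"} | categorize_residue(resname)),
                            )
                        )
    return ContactScenario(
        contacts=contacts, alignment=alignment, author_offsets=offsets,
        consensus_map=cmap, planted_columns=planted_by_receptor,
    )


def gen_gmt(
    config: SyntheticConfig, universe: list[str] | None = None
) -> tuple[list[PathwayAnnotation], str]:
    """Pathway annotation with one planted enriched pathway.

    The planted pathway holds ``planted_overlap`` hot-target genes plus
    random filler; the remaining pathways are uniform draws from the
    universe. Returns (annotations, planted pathway id).
    """
    rng = substream(config.seed, "pathways")
    uni = list(universe) if universe is not None else config.gene_universe
    hot = [g for g in config.hot_targets if g in uni]
    overlap = min(config.planted_overlap, len(hot))
    background = [g for g in uni if g not in set(hot)]
    filler_n = config.planted_pathway_size - overlap
    filler = rng.choice(len(background), size=filler_n, replace=False)
    planted_genes = frozenset(hot[:overlap]) | frozenset(background[i] for i in filler)
    annotations = [
        PathwayAnnotation("PW0000", "planted pathway", frozenset(planted_genes))
    ]
    for i in range(1, config.n_pathways):
        size = int(rng.integers(10, 31))
        members = rng.choice(len(uni), size=size, replace=False)
        annotations.append(
            PathwayAnnotation(
                f"PW{i:04d}", f"random pathway {i}",
                frozenset(uni[j] for j in members),
            )
        )
    return annotations, "PW0000"
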