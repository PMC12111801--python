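"""Metabolite ingestion, size filters, descriptors and BOILED-Egg permeability.

The funnel's first stage takes raw SMILES, canonicalizes them, discards
molecules with four or fewer heavy atoms or canonical SMILES longer than 200
characters, computes the two descriptors the BOILED-Egg model needs
(Wildman-Crippen WLOGP and Ertl TPSA including S/P contributions), and
classifies gastrointestinal absorption and blood-brain-barrier permeation by
ellipse membership in (TPSA, WLOGP) space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Sequence

import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

DEFAULT_MIN_HEAVY_ATOMS = 5
DEFAULT_MAX_SMILES_LENGTH = 200


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class DescriptorsUnsetError(ValueError):
    """Raised when permeability is requested before descriptors are computed."""


@dataclass(frozen=True)
class MetaboliteRecord:
    """One compound: identifiers, canonical form and descriptors.

    ``wlogp``/``tpsa`` stay ``None`` until :func:`compute_descriptors` runs.
    """

    id: str
    smiles: str
    canonical_smiles: str
    heavy_atom_count: int
    smiles_length: int
    wlogp: float | None = None
    tpsa: float | None = None
    source: str = "synthetic"


@dataclass(frozen=True)
class RejectedRecord:
    id: str
    smiles: str
    reason: str  # unparseable | too_few_atoms | too_long | duplicate


@dataclass(frozen=True)
class PermeabilityCall:
    metabolite_id: str
    gi_absorption: str  # "high" | "low"
    bbb_permeant: bool


@dataclass(frozen=True)
class EllipseParams:
    """Axis-aligned-then-rotated ellipse in (TPSA, WLOGP) space.

    ``rotation`` is in radians, anticlockwise, about the center.
    """

    name: str
    center_tpsa: float
    center_wlogp: float
    semi_axis_tpsa: float
    semi_axis_wlogp: float
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if self.semi_axis_tpsa <= 0 or self.semi_axis_wlogp <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    def contains(self, tpsa: float, wlogp: float) -> bool:
        """Closed-region membership test (boundary counts as inside)."""
        dx = tpsa - self.center_tpsa
        dy = wlogp - self.center_wlogp
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        u = (dx * c + dy * s) / self.semi_axis_tpsa
        v = (-dx * s + dy * c) / self.semi_axis_wlogp
        return u * u + v * v <= 1.0


def load_ellipses(path: str | None = None) -> dict[str, EllipseParams]:
    """Load GI/BBB ellipse parameters; defaults to the packaged config."""
    if path is None:
        text = resources.files("metafunnel.data").joinpath("ellipses.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {name: EllipseParams(name=name, **params) for name, params in raw.items()}


def parse_and_canonicalize(
    raw: str, id: str | None = None, source: str = "synthetic"
) -> MetaboliteRecord:
    """Parse a SMILES string into a record with the canonical form populated.

    Raises :class:`SmilesParseError` on empty or unparseable input; batch
    callers catch it and log a :class:`RejectedRecord` instead of aborting.
    """
    if not raw or not raw.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {raw!r}")
    canonical = Chem.MolToSmiles(mol)
    return MetaboliteRecord(
        id=id if id is not None else canonical,
        smiles=raw,
        canonical_smiles=canonical,
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        smiles_length=len(canonical),
        source=source,
    )


def parse_batch(
    entries: Iterable[tuple[str, str] | tuple[str, str, str]],
) -> tuple[list[MetaboliteRecord], list[RejectedRecord]]:
    """Parse (id, smiles[, source]) tuples, collecting failures as rejections."""
    records: list[MetaboliteRecord] = []
    rejected: list[RejectedRecord] = []
    for entry in entries:
        mid, smi = entry[0], entry[1]
        source = entry[2] if len(entry) > 2 else "synthetic"
        try:
            records.append(parse_and_canonicalize(smi, id=mid, source=source))
        except SmilesParseError:
            rejected.append(RejectedRecord(id=mid, smiles=smi, reason="unparseable"))
    return records, rejected


def filter_metabolites(
    records: Sequence[MetaboliteRecord],
    min_heavy_atoms: int = DEFAULT_MIN_HEAVY_ATOMS,
    max_smiles_length: int = DEFAULT_MAX_SMILES_LENGTH,
) -> tuple[list[MetaboliteRecord], list[RejectedRecord]]:
    """Apply the size rules and deduplicate on canonical SMILES.

    Keeps records with at least ``min_heavy_atoms`` heavy atoms (the "four
    atoms or fewer" discrimination counts heavy atoms) and canonical SMILES of
    at most ``max_smiles_length`` characters; later duplicates of an already
    kept canonical form are rejected with reason ``duplicate``.
    """
    kept: list[MetaboliteRecord] = []
    rejected: list[RejectedRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.heavy_atom_count < min_heavy_atoms:
            rejected.append(RejectedRecord(rec.id, rec.smiles, "too_few_atoms"))
        elif rec.smiles_length > max_smiles_length:
            rejected.append(RejectedRecord(rec.id, rec.smiles, "too_long"))
        elif rec.canonical_smiles in seen:
            rejected.append(RejectedRecord(rec.id, rec.smiles, "duplicate"))
        else:
            seen.add(rec.canonical_smiles)
            kept.append(rec)
    return kept, rejected


def compute_descriptors(record: MetaboliteRecord) -> MetaboliteRecord:
    """Fill in WLOGP (Wildman-Crippen) and TPSA (Ertl, with S/P terms).

    The S/P contributions are included for parity with the descriptor set the
    BOILED-Egg model was fitted on.
    """
    mol = Chem.MolFromSmiles(record.canonical_smiles)
    if mol is None:  # canonical form always reparses; guard for corrupt records
        raise SmilesParseError(f"unparseable SMILES: {record.canonical_smiles!r}")
    wlogp = Crippen.MolLogP(mol)
    tpsa = rdMolDescriptors.CalcTPSA(mol, includeSandP=True)
    return replace(record, wlogp=wlogp, tpsa=tpsa)


def classify_permeability(
    record: MetaboliteRecord,
    gi: EllipseParams,
    bbb: EllipseParams,
) -> PermeabilityCall:
    """BOILED-Egg call: GI = white-ellipse membership, BBB = yolk membership.

    BBB permeation is only reported within the GI-absorbed subset (funnel
    convention): a point inside the yolk but outside the white region is
    called ``gi_absorption="low", bbb_permeant=False``.
    """
    if record.wlogp is None or record.tpsa is None:
        raise DescriptorsUnsetError(f"descriptors unset for {record.id}")
    gi_high = gi.contains(record.tpsa, record.wlogp)
    in_bbb = bbb.contains(record.tpsa, record.wlogp)
    return PermeabilityCall(
        metabolite_id=record.id,
        gi_absorption="high" if gi_high else "low",
        bbb_permeant=bool(gi_high and in_bbb),
    )


def funnel_counts(calls: Sequence[PermeabilityCall]) -> tuple[int, int, int]:
    n_gi = sum(1 for c in calls if c.gi_absorption == "high")
    n_bbb = sum(1 for c in calls if c.bbb_permeant)
    return len(calls), n_gi, n_bbb


def funnel_report(
    n_total: int, n_gi: int, n_bbb: int | None = None, rounding: str = "decimal"
) -> dict:
    """Summarize the absorption funnel as counts plus percentages.

    ``pct_gi`` is rounded to 2 decimals and ``pct_bbb_of_gi`` (BBB within the
    GI-absorbed subset) to 1 decimal; ``rounding="integer"`` reproduces
    whole-percent reporting. ``pct_bbb_of_gi`` is ``None`` when ``n_gi`` is
    zero or ``n_bbb`` is not supplied.
    """
    if n_total <= 0:
        raise ValueError("funnel report requires n_total > 0")
    if rounding not in ("decimal", "integer"):
        raise ValueError(f"unknown rounding mode: {rounding!r}")
    pct_gi = 100.0 * n_gi / n_total
    pct_gi = round(pct_gi) if rounding == "integer" else round(pct_gi, 2)
    pct_bbb = None
    if n_bbb is not None and n_gi > 0:
        pct_bbb = 100.0 * n_bbb / n_gi
        pct_bbb = round(pct_bbb) if rounding == "integer" else round(pct_bbb, 1)
    return {
        "n_total": n_total,
        "n_gi": n_gi,
        "n_bbb": n_bbb,
        "pct_gi": pct_gi,
        "pct_bbb_of_gi": pct_bbb,
    }


def funnel_report_from_calls(
    calls: Sequence[PermeabilityCall], rounding: str = "decimal"
) -> dict:
    return funnel_report(*funnel_counts(calls), rounding=rounding)
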