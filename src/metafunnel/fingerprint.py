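"""Ligand-residue interaction fingerprints on consensus numbering.

Contacts between ligand and receptor heavy atoms (from complex structures or
tabulated contact lists) are mapped from each receptor's author residue
numbering onto multiple-sequence-alignment consensus columns, so equivalent
pocket positions line up across nuclear-receptor isoforms. Per consensus
column, the contact frequency over the analyzed ligand panel yields the
high-frequency residue sets (>50% and >75% of ligands), pharmacology residue
classes (agonist / antagonist-only / isoform-unique) and directional
coincidence rates between isoforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# Interaction-chemistry residue classes (including force-field protonation
# variants such as HIE/HID/HIP for histidine).
HYDROPHOBIC = {"PHE", "LEU", "ILE", "TYR", "TRP", "VAL", "MET", "PRO", "CYS", "ALA", "CYX"}
AROMATIC = {"PHE", "TYR", "TRP", "TYO"}
POLAR = {
    "ARG", "ASP", "GLU", "HIS", "ASN", "GLN", "LYS", "SER", "THR",
    "ARN", "ASH", "GLH", "HID", "HIE", "LYN",
}
CHARGED = {"ARG", "ASP", "GLU", "LYS", "HIP", "CYT", "SRO", "TYO", "THO"}

VARIANT_PARENT = {
    "HIE": "HIS", "HID": "HIS", "HIP": "HIS",
    "ASH": "ASP", "GLH": "GLU", "LYN": "LYS",
    "CYX": "CYS", "ARN": "ARG", "CYT": "CYS",
    "TYO": "TYR", "SRO": "SER", "THO": "THR",
}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
KNOWN_RESIDUES = STANDARD_AA | set(VARIANT_PARENT)

BACKBONE_ATOMS = {"N", "CA", "C", "O"}
DEFAULT_CONTACT_CUTOFF = 4.0  # Angstrom, heavy-atom to heavy-atom, closed interval
HBOND_CUTOFF = 3.5  # donor-acceptor heavy-atom distance, no angle term

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


class UnknownResidueError(ValueError):
    pass


@dataclass(frozen=True)
class ResidueContact:
    ligand_id: str
    receptor_id: str
    author_resnum: int
    residue_name: str
    categories: frozenset[str]


def categorize_residue(residue_name: str) -> set[str]:
    """Chemistry categories for a residue (a residue may carry several).

    Protonation variants fall back to their parent identity for the
    hydrophobic/aromatic classes; the polar/charged lists name their variants
    explicitly and are taken as-is.
    """
    name = residue_name.strip().upper()
    if name not in KNOWN_RESIDUES:
        raise UnknownResidueError(f"unknown residue code: {residue_name!r}")
    parent = VARIANT_PARENT.get(name, name)
    cats: set[str] = set()
    if name in HYDROPHOBIC or parent in HYDROPHOBIC:
        cats.add("hydrophobic")
    if name in AROMATIC or parent in AROMATIC:
        cats.add("aromatic")
    if name in POLAR:
        cats.add("polar")
    if name in CHARGED:
        cats.add("charged")
    return cats


def contacts_from_complex(
    structure,
    ligand_resname: str,
    ligand_id: str | None = None,
    receptor_id: str = "receptor",
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    ligand_chain: str | None = None,
) -> list[ResidueContact]:
    """Extract residue contacts from a protein-ligand complex.

    ``structure`` is a biotite ``AtomArray``. A receptor residue is a contact
    when any of its heavy atoms lies within ``cutoff`` (closed interval) of
    any ligand heavy atom. Backbone/sidechain flags follow atom-name
    convention (N, CA, C, O = backbone); a polar-polar heavy-atom pair within
    3.5 A additionally flags hydrogen-bond donor/acceptor capability.
    """
    import biotite.structure as struc

    heavy = structure[structure.element != "H"]
    lig_mask = heavy.res_name == ligand_resname
    if ligand_chain is not None:
        lig_mask &= heavy.chain_id == ligand_chain
    lig = heavy[lig_mask]
    if lig.array_length() == 0:
        raise ValueError(f"ligand {ligand_resname!r} not found in structure")
    if len(set(zip(lig.chain_id.tolist(), lig.res_id.tolist()))) > 1:
        raise ValueError(
            f"multiple ligands match {ligand_resname!r}; specify ligand_chain"
        )
    rec = heavy[struc.filter_amino_acids(heavy)]
    contacts: list[ResidueContact] = []
    lid = ligand_id if ligand_id is not None else ligand_resname
    res_ids, res_names = struc.get_residues(rec)
    for rid, rname in zip(res_ids.tolist(), res_names.tolist()):
        res_atoms = rec[rec.res_id == rid]
        d = np.linalg.norm(
            res_atoms.coord[:, None, :] - lig.coord[None, :, :], axis=-1
        )
        if d.min() > cutoff:
            continue
        close = d.min(axis=1) <= cutoff
        atom_names = res_atoms.atom_name[close]
        cats = {"any"}
        if any(a in BACKBONE_ATOMS for a in atom_names):
            cats.add("backbone")
        if any(a not in BACKBONE_ATOMS for a in atom_names):
            cats.add("sidechain")
        try:
            cats |= categorize_residue(str(rname))
        except UnknownResidueError:
            pass  # non-standard receptor residue: keep geometric flags only
        polar_res = res_atoms[np.isin(res_atoms.element, ("N", "O"))]
        polar_lig = lig[np.isin(lig.element, ("N", "O"))]
        if polar_res.array_length() and polar_lig.array_length():
            dp = np.linalg.norm(
                polar_res.coord[:, None, :] - polar_lig.coord[None, :, :], axis=-1
            )
            if dp.min() <= HBOND_CUTOFF:
                cats |= {"hbond_donor", "hbond_acceptor"}
        contacts.append(
            ResidueContact(
                ligand_id=lid,
                receptor_id=receptor_id,
                author_resnum=int(rid),
                residue_name=str(rname),
                categories=frozenset(cats),
            )
        )
    return contacts


# ---------------------------------------------------------------------------
# Global alignment (Needleman-Wunsch, affine gaps, deterministic tie-breaks)
# ---------------------------------------------------------------------------

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

_NEG = float("-inf")


def pairwise_align(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -1.0,
    gap_extend: float = -1.0,
    substitution: Mapping[tuple[str, str], float] | None = None,
) -> tuple[str, str, float]:
    """Needleman-Wunsch global alignment with affine gap penalties.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend`` (both are
    scores, i.e. negative). Tie-breaking in the traceback is deterministic:
    prefer the diagonal move, then the vertical (gap in ``seq_b``), then the
    horizontal. Returns (aligned_a, aligned_b, score).
    """
    for seq in (seq_a, seq_b):
        if not seq:
            raise ValueError("sequences must be non-empty")
        bad = set(seq.upper()) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    a, b = seq_a.upper(), seq_b.upper()
    la, lb = len(a), len(b)

    def sub(x: str, y: str) -> float:
        if substitution is not None:
            return substitution[(x, y)] if (x, y) in substitution else substitution[(y, x)]
        return match if x == y else mismatch

    # M: a[i-1] aligned to b[j-1]; X: gap in b (vertical); Y: gap in a (horizontal)
    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)
    Y = np.full((la + 1, lb + 1), _NEG)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, lb + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = sub(a[i - 1], b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    score = max(M[la, lb], X[la, lb], Y[la, lb])
    # deterministic traceback: diagonal, then vertical, then horizontal
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    state = "M" if M[i, j] == score else ("X" if X[i, j] == score else "Y")
    while i > 0 or j > 0:
        if state == "M":
            s = sub(a[i - 1], b[j - 1])
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = M[i, j] - s
            i, j = i - 1, j - 1
            state = "M" if M[i, j] == prev else ("X" if X[i, j] == prev else "Y")
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            if i > 1 or j > 0:
                if M[i - 1, j] + gap_open == X[i, j]:
                    state = "M"
                elif X[i - 1, j] + gap_extend == X[i, j]:
                    state = "X"
                else:
                    state = "Y"
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            if j > 1 or i > 0:
                if M[i, j - 1] + gap_open == Y[i, j]:
                    state = "M"
                elif Y[i, j - 1] + gap_extend == Y[i, j]:
                    state = "Y"
                else:
                    state = "X"
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)


# ---------------------------------------------------------------------------
# Consensus numbering
# ---------------------------------------------------------------------------


@dataclass
class ConsensusMap:
    """Per-receptor mapping author residue number -> 1-based alignment column."""

    maps: dict[str, dict[int, int]]

    def to_consensus(self, receptor_id: str, author_resnum: int) -> int:
        try:
            return self.maps[receptor_id][author_resnum]
        except KeyError:
            raise KeyError(
                f"residue {author_resnum} of {receptor_id} not resolvable "
                "through the consensus map"
            ) from None

    def invert(self, receptor_id: str) -> dict[int, int]:
        return {col: num for num, col in self.maps[receptor_id].items()}


def consensus_map_from_alignment(
    alignment: Mapping[str, str], author_offsets: Mapping[str, int]
) -> ConsensusMap:
    """Build consensus numbering from an MSA.

    ``alignment`` maps receptor id to its aligned (gapped) sequence; the i-th
    non-gap character of a sequence is residue ``author_offset + i - 1`` and
    maps to its 1-based alignment column.
    """
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ValueError("aligned sequences differ in length")
    if len(alignment) != len(set(alignment)):
        raise ValueError("duplicated receptor ids in alignment")
    maps: dict[str, dict[int, int]] = {}
    for rec, seq in alignment.items():
        offset = author_offsets[rec]
        mapping: dict[int, int] = {}
        resnum = offset
        for col, char in enumerate(seq, start=1):
            if char != "-":
                mapping[resnum] = col
                resnum += 1
        maps[rec] = mapping
    return ConsensusMap(maps)


def consensus_map_from_table(table: pd.DataFrame) -> ConsensusMap:
    """Consensus map from a residue table with columns
    (receptor, consensus_column, residue), residue like ``C276``."""
    maps: dict[str, dict[int, int]] = {}
    for _, row in table.dropna(subset=["residue"]).iterrows():
        num = int("".join(ch for ch in str(row["residue"]) if ch.isdigit()))
        maps.setdefault(str(row["receptor"]), {})[num] = int(row["consensus_column"])
    return ConsensusMap(maps)


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------


@dataclass
class ContactFingerprint:
    """Binary consensus-column x ligand matrix for one receptor."""

    receptor_id: str
    matrix: pd.DataFrame  # index: consensus column (int), columns: ligand_id (bool)
    dominant_category: dict[int, str] = field(default_factory=dict)

    @property
    def frequency(self) -> pd.Series:
        """Per-column contacted fraction over the full ligand panel."""
        return self.matrix.mean(axis=1)

    def to_tsv(self, path) -> None:
        out = self.matrix.astype(int)
        out.index.name = "consensus_column"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, receptor_id: str) -> "ContactFingerprint":
        df = pd.read_csv(path, sep="\t", index_col="consensus_column")
        return cls(receptor_id=receptor_id, matrix=df.astype(bool))


def build_fingerprint(
    contacts: Sequence[ResidueContact],
    cmap: ConsensusMap,
    ligand_universe: Sequence[str],
    receptor_id: str,
) -> ContactFingerprint:
    """Binary fingerprint over the full ligand panel for one receptor.

    Ligands with zero contacts still count in the frequency denominator.
    Unmappable author residue numbers raise, naming the residues.
    """
    rec_contacts = [c for c in contacts if c.receptor_id == receptor_id]
    unmappable = sorted(
        {
            c.author_resnum
            for c in rec_contacts
            if c.author_resnum not in cmap.maps.get(receptor_id, {})
        }
    )
    if unmappable:
        raise KeyError(
            f"unmappable residues for {receptor_id}: {unmappable}"
        )
    cols = sorted({cmap.to_consensus(receptor_id, c.author_resnum) for c in rec_contacts})
    matrix = pd.DataFrame(False, index=cols, columns=list(ligand_universe))
    cat_votes: dict[int, list[str]] = {}
    for c in rec_contacts:
        if c.ligand_id not in matrix.columns:
            continue
        col = cmap.to_consensus(receptor_id, c.author_resnum)
        matrix.loc[col, c.ligand_id] = True
        for cat in sorted(c.categories - {"any", "backbone", "sidechain"}):
            cat_votes.setdefault(col, []).append(cat)
    dominant = {
        col: max(set(votes), key=lambda v: (votes.count(v), v))
        for col, votes in cat_votes.items()
    }
    return ContactFingerprint(receptor_id=receptor_id, matrix=matrix,
                              dominant_category=dominant)


def threshold_residue_sets(
    fp: ContactFingerprint, thresholds: Sequence[float] = (0.50, 0.75)
) -> dict[float, set[int]]:
    """Consensus columns whose contact frequency strictly exceeds each threshold."""
    freq = fp.frequency
    return {t: set(freq.index[freq > t]) for t in thresholds}


def coincidence_rate(set_a: Iterable[int], set_b: Iterable[int]) -> float:
    """Directional overlap: 100 * |A intersect B| / |A|.

    The denominator is the first-named receptor's set, so the rate is not
    symmetric.
    """
    a, b = set(set_a), set(set_b)
    if not a:
        raise ValueError("empty reference set")
    return 100.0 * len(a & b) / len(a)


def classify_pharmacology_sets(
    contacts_by_receptor: Mapping[str, Mapping[str, set[int]]],
    ligand_classes: Mapping[str, str],
    agonist_classes: Sequence[str] = ("drug_agonist",),
    antagonist_classes: Sequence[str] = ("drug_antagonist",),
) -> dict[str, dict[str, set[int]]]:
    """Pharmacology residue sets per receptor, in consensus space.

    ``contacts_by_receptor`` maps receptor -> ligand -> contacted consensus
    columns. Returns, per receptor, ``agonist_residues`` (contacted by any
    agonist-class ligand), ``antagonist_residues``, ``antagonist_only``
    (antagonist-contacted, never agonist-contacted) and ``isoform_unique``
    (columns contacted in exactly one receptor).
    """
    classes = set(ligand_classes.values())
    if not (classes & set(agonist_classes)) or not (classes & set(antagonist_classes)):
        raise ValueError("need at least one agonist-class and one antagonist-class ligand")
    contacted_per_receptor = {
        rec: set().union(*ligmap.values()) if ligmap else set()
        for rec, ligmap in contacts_by_receptor.items()
    }
    out: dict[str, dict[str, set[int]]] = {}
    for rec, ligmap in contacts_by_receptor.items():
        ago: set[int] = set()
        anta: set[int] = set()
        for lig, cols in ligmap.items():
            cls = ligand_classes.get(lig)
            if cls in agonist_classes:
                ago |= cols
            if cls in antagonist_classes:
                anta |= cols
        unique = {
            col
            for col in contacted_per_receptor[rec]
            if sum(col in other for other in contacted_per_receptor.values()) == 1
        }
        out[rec] = {
            "agonist_residues": ago,
            "antagonist_residues": anta,
            "antagonist_only": anta - ago,
            "isoform_unique": unique,
        }
    return out


# ---------------------------------------------------------------------------
# Packaged residue-table fixtures (printed consensus residue sets)
# ---------------------------------------------------------------------------


def load_residue_table(which: str) -> pd.DataFrame:
    """Packaged consensus residue tables for the PPAR ('a') and RXR ('b') panels.

    Columns: receptor, consensus_column, residue (author label like C276),
    gt75 (residue contacts >75% of the analyzed ligands), role (agonist /
    antagonist / specific row of origin).
    """
    name = {"a": "table4a_ppar_residues.tsv", "b": "table4b_rxr_residues.tsv"}[which]
    with resources.files("metafunnel.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["gt75"] = df["gt75"].astype(bool)
    return df


def residue_sets_from_table(table: pd.DataFrame) -> dict[str, dict[str, set[int]]]:
    """High-frequency consensus-column sets per receptor from a residue table.

    The agonist rows list the residues contacting >50% of ligands; the bold
    subset (gt75) contacts >75%.
    """
    out: dict[str, dict[str, set[int]]] = {}
    for rec, sub in table.groupby("receptor"):
        ago = sub[sub["role"] == "agonist"]
        out[str(rec)] = {
            "gt50": set(ago["consensus_column"].astype(int)),
            "gt75": set(ago.loc[ago["gt75"], "consensus_column"].astype(int)),
        }
    return out
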