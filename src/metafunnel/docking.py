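"""Docking-score triage: percentile thresholds, hit selection, group tests.

Docking scores are unitless Glide-like values where more negative means
stronger predicted binding. Per receptor, the strongest 5% of scores define
the affinity cutoff ("95th percentile" of binding strength); a ligand is a hit
when it is brain-permeant and scores at or below the cutoff for at least one
receptor. Score distributions across receptors or metabolite classes are
compared with Kruskal-Wallis plus Dunn's post-hoc (non-parametric) and a
two-way ANOVA with Tukey HSD (parametric).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

LIGAND_CLASSES = (
    "Kb",
    "SCFA",
    "MCFA",
    "LCFA",
    "MUFA",
    "PUFA",
    "vitaminA",
    "indole",
    "drug_agonist",
    "drug_antagonist",
    "screen",
)

MIN_GROUP_SIZE = 4  # classes smaller than this are left out of inferential tests


@dataclass
class DockingMatrix:
    """Ligand x receptor score grid; missing scores allowed (NaN)."""

    scores: pd.DataFrame  # index = ligand_id, columns = receptor_id
    ligand_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.ligand_class.values()) - set(LIGAND_CLASSES)
        if bad:
            raise ValueError(f"unknown ligand classes: {sorted(bad)}")

    @property
    def ligands(self) -> list[str]:
        return list(self.scores.index)

    @property
    def receptors(self) -> list[str]:
        return list(self.scores.columns)

    def long(self) -> pd.DataFrame:
        df = (
            self.scores.stack()
            .rename("score")
            .rename_axis(["ligand_id", "receptor_id"])
            .reset_index()
        )
        df["ligand_class"] = df["ligand_id"].map(self.ligand_class)
        return df


def percentile_cutoff(scores: Sequence[float], q: float = 0.05) -> float:
    """Linear-interpolation quantile of the score distribution.

    With scores ascending (most negative = strongest), ``q=0.05`` returns the
    boundary of the strongest 5% — the "95th percentile of binding affinity".
    """
    arr = np.asarray([s for s in np.asarray(scores, dtype=float) if not np.isnan(s)])
    if arr.size == 0:
        raise ValueError("no scores supplied")
    if not 0 < q < 1:
        raise ValueError("q must lie strictly between 0 and 1")
    return float(np.quantile(arr, q, method="linear"))


def compute_thresholds(matrix: DockingMatrix, q: float = 0.05) -> dict[str, float]:
    """Per-receptor affinity cutoffs at quantile ``q``."""
    return {r: percentile_cutoff(matrix.scores[r].dropna(), q) for r in matrix.receptors}


def select_hits(
    matrix: DockingMatrix,
    thresholds: Mapping[str, float],
    permeable: Iterable[str],
) -> pd.DataFrame:
    """Hit table: rows pass iff the ligand is BBB-permeant and score <= cutoff.

    Ties at the cutoff count as hits (affinity at least as strong as the
    limit). Returns one row per observed (ligand, receptor) score with
    ``passes`` and ``bbb_permeant`` flags, receptor-wise sorted by score.
    """
    missing = set(matrix.receptors) - set(thresholds)
    if missing:
        raise KeyError(f"receptors missing from thresholds: {sorted(missing)}")
    permeable = set(permeable)
    rows = matrix.long()
    rows["bbb_permeant"] = rows["ligand_id"].isin(permeable)
    rows["cutoff"] = rows["receptor_id"].map(thresholds)
    rows["passes"] = rows["bbb_permeant"] & (rows["score"] <= rows["cutoff"])
    return rows.sort_values(["receptor_id", "score"], kind="stable").reset_index(drop=True)


def hit_ligands(hits: pd.DataFrame) -> list[str]:
    """Ligands passing for at least one receptor."""
    return sorted(hits.loc[hits["passes"], "ligand_id"].unique())


def _clean_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        out[name] = arr
    return out


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]], p_adjust: str = "fdr_bh"
) -> pd.DataFrame:
    """Dunn's pairwise rank-based z-tests after a Kruskal-Wallis test.

    Uses pooled midranks with the tie correction
    sigma^2 = (N(N+1)/12 - sum(t^3 - t)/(12(N-1))) * (1/n_i + 1/n_j).
    Two-sided p-values are adjusted with Benjamini-Hochberg by default
    (``p_adjust="bonferroni"`` available).
    """
    groups = _clean_groups(groups)
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    rank_by_group: dict[str, np.ndarray] = {}
    offset = 0
    for g in names:
        size = groups[g].size
        rank_by_group[g] = ranks[offset : offset + size]
        offset += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for a, b in itertools.combinations(names, 2):
        na, nb = groups[a].size, groups[b].size
        diff = rank_by_group[a].mean() - rank_by_group[b].mean()
        se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
        z = diff / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_value": p})
    df = pd.DataFrame(rows)
    if len(df):
        method = {"fdr_bh": "fdr_bh", "bonferroni": "bonferroni"}[p_adjust]
        df["p_adjusted"] = multipletests(df["p_value"], method=method)[1]
    return df


def compare_groups_kw(
    groups: Mapping[str, Sequence[float]],
    p_adjust: str = "fdr_bh",
    min_group_size: int = 2,
) -> dict:
    """Kruskal-Wallis H (midrank tie correction) plus Dunn's post-hoc table."""
    groups = _clean_groups(groups)
    groups = {g: v for g, v in groups.items() if v.size >= min_group_size}
    if len(groups) < 2:
        raise ValueError("need at least two groups with enough observations")
    h, p = stats.kruskal(*groups.values())
    return {
        "H": float(h),
        "p_value": float(p),
        "df": len(groups) - 1,
        "groups": {g: int(v.size) for g, v in groups.items()},
        "dunn": dunn_posthoc(groups, p_adjust=p_adjust),
    }


def grouped_scores(
    matrix: DockingMatrix, by: str = "receptor", min_group_size: int = MIN_GROUP_SIZE
) -> dict[str, np.ndarray]:
    """Score vectors grouped by receptor or ligand class.

    Classes below ``min_group_size`` ligands (e.g. ketone bodies, retinoids in
    a small panel) are dropped from inferential comparisons.
    """
    long = matrix.long().dropna(subset=["score"])
    if by == "receptor":
        col = "receptor_id"
    elif by == "class":
        col = "ligand_class"
        sizes = long.groupby(col)["ligand_id"].nunique()
        keep = sizes[sizes >= min_group_size].index
        long = long[long[col].isin(keep)]
    else:
        raise ValueError("by must be 'receptor' or 'class'")
    return {str(g): sub["score"].to_numpy() for g, sub in long.groupby(col)}


def compare_groups_anova(matrix: DockingMatrix) -> dict:
    """Two-way ANOVA (class x receptor) with Tukey HSD post-hoc tables.

    Requires every class x receptor cell to hold at least one observation.
    """
    long = matrix.long().dropna(subset=["score", "ligand_class"])
    cells = long.groupby(["ligand_class", "receptor_id"], observed=True).size()
    classes = long["ligand_class"].unique()
    receptors = long["receptor_id"].unique()
    if len(cells) < len(classes) * len(receptors):
        raise ValueError("unbalanced design: empty class x receptor cell")
    terms = []
    if len(classes) > 1:
        terms.append("C(ligand_class)")
    if len(receptors) > 1:
        terms.append("C(receptor_id)")
    if not terms:
        raise ValueError("need at least two levels in one factor")
    formula = "score ~ " + (" * ".join(terms))
    model = ols(formula, data=long).fit()
    table = anova_lm(model, typ=2)
    if np.isclose(long["score"].var(ddof=0), 0.0):
        # degenerate constant response: no variance to apportion
        table["F"] = [0.0] * (len(table) - 1) + [np.nan]
        table["PR(>F)"] = [1.0] * (len(table) - 1) + [np.nan]
    tukey = {}
    if len(classes) > 1:
        tukey["class"] = pairwise_tukeyhsd(long["score"], long["ligand_class"])
    if len(receptors) > 1:
        tukey["receptor"] = pairwise_tukeyhsd(long["score"], long["receptor_id"])
    return {"anova": table, "tukey": tukey, "n": int(len(long))}


def summarize_distribution(matrix: DockingMatrix) -> pd.DataFrame:
    """Per-receptor order statistics with the same quantile convention as
    :func:`percentile_cutoff`."""
    rows = []
    for r in matrix.receptors:
        vals = matrix.scores[r].dropna().to_numpy()
        if vals.size == 0:
            continue
        qs = np.quantile(vals, [0.05, 0.25, 0.5, 0.75, 0.95], method="linear")
        rows.append(
            {
                "receptor_id": r,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "median": float(qs[2]),
                "p5": float(qs[0]),
                "p25": float(qs[1]),
                "p75": float(qs[3]),
                "p95": float(qs[4]),
            }
        )
    return pd.DataFrame(rows)
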