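"""Single-sample gene-set enrichment (ssGSEA) and immune-score analysis.

The per-sample enrichment score is the integrated running sum of a weighted
walk over the sample's expression ranking: identifiers are ranked by
descending expression (average ranks for ties), in-set identifiers add
rank_weight^alpha normalised by the total in-set weight, out-of-set
identifiers subtract 1/(N - set size), and the score is the sum of the
running sum over all positions (the ssGSEA convention, not the max-deviation
GSEA statistic). alpha defaults to 0.25.

On top of that sit: an additive immune score over user-supplied signature
sets, a Mann-Whitney comparison of per-sample scores between groups, the
Pearson correlation of mean anti-tumor vs pro-tumor scores within each
group, row z-scoring for infiltration heatmaps, and a one-sided Fisher
exact over-representation test for arbitrary annotation sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AbundanceMatrix, GeneSetCollection

__all__ = [
    "ScoreMatrix",
    "ssgsea_sample",
    "score_collection",
    "immune_score",
    "compare_groups",
    "anti_pro_correlation",
    "zscore_rows",
    "fisher_ora",
]

ANTI, PRO, OTHER = "anti_tumor", "pro_tumor", "other"


@dataclass
class ScoreMatrix:
    """Gene-set x sample enrichment scores."""

    scores: pd.DataFrame  # index set_name, columns sample_id
    normalization: str = "raw"

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def ssgsea_sample(expression, gene_set, alpha: float = 0.25) -> float:
    """Enrichment score of one gene set in one sample.

    ``expression`` maps identifier -> value (dict or Series). The score is
    rank-based, hence invariant under strictly increasing transforms of the
    sample's values.
    """
    s = pd.Series(expression, dtype=float)
    ids = list(s.index)
    n = len(ids)
    in_set = set(gene_set) & set(ids)
    if not in_set:
        raise ValueError(f"gene set has no overlap with the measured identifiers")
    if len(in_set) == n:
        raise ValueError("gene set covers every measured identifier")
    # weight: average rank with the highest expression getting weight N
    weight = s.rank(ascending=True, method="average")
    # walk from the highest expression down; ties broken by id for determinism
    order = sorted(ids, key=lambda g: (-s[g], g))
    w_alpha = weight.pow(alpha)
    denom_in = float(w_alpha[list(in_set)].sum())
    dec = 1.0 / (n - len(in_set))
    steps = np.array(
        [w_alpha[g] / denom_in if g in in_set else -dec for g in order]
    )
    return float(np.cumsum(steps).sum())


def score_collection(
    matrix: AbundanceMatrix, sets: GeneSetCollection, alpha: float = 0.25
) -> ScoreMatrix:
    """ssGSEA score for every (set, sample) pair of a completed matrix."""
    if matrix.missing_mask.any():
        raise ValueError("score_collection requires a completed matrix")
    measured = set(matrix.protein_ids)
    bad = [
        name
        for name, members in sets.sets.items()
        if not (set(members) & measured) or set(matrix.protein_ids) <= set(members)
    ]
    if bad:
        raise ValueError(f"gene sets failing the overlap preconditions: {bad}")
    values = matrix.to_dataframe()
    scores = pd.DataFrame(
        index=pd.Index(sets.names(), name="set_name"),
        columns=matrix.sample_ids,
        dtype=float,
    )
    for sample in matrix.sample_ids:
        expr = values[sample]
        for name, members in sets.sets.items():
            scores.loc[name, sample] = ssgsea_sample(expr, members, alpha)
    return ScoreMatrix(scores, "raw")


def immune_score(score_matrix: ScoreMatrix, signature_sets) -> pd.Series:
    """Per-sample immune score: sum of the named signature sets' scores."""
    signature_sets = list(signature_sets)
    unknown = [s for s in signature_sets if s not in score_matrix.scores.index]
    if unknown:
        raise ValueError(f"unknown signature sets: {unknown}")
    out = score_matrix.scores.loc[signature_sets].sum(axis=0)
    out.name = "immune_score"
    return out


def compare_groups(scores: pd.Series, group_of: dict[str, str]):
    """Two-sided Mann-Whitney comparison of per-sample scores between groups.

    Returns (p_value, {group: mean}, direction) where direction names the
    group with the larger mean.
    """
    groups = sorted(set(group_of[s] for s in scores.index))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    ga, gb = groups
    a = scores[[s for s in scores.index if group_of[s] == ga]].to_numpy(float)
    b = scores[[s for s in scores.index if group_of[s] == gb]].to_numpy(float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 samples")
    if np.ptp(np.concatenate([a, b])) == 0:
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    means = {ga: float(a.mean()), gb: float(b.mean())}
    direction = max(means, key=means.get)
    return p, means, direction


def anti_pro_correlation(
    score_matrix: ScoreMatrix,
    annotation: dict[str, str],
    group_of: dict[str, str],
) -> dict[str, float]:
    """Per-group Pearson r between mean anti-tumor and mean pro-tumor scores.

    For each sample the anti-tumor and pro-tumor set scores are averaged;
    r is the within-group correlation of those two per-sample vectors.
    """
    anti = [s for s in score_matrix.set_names if annotation.get(s) == ANTI]
    pro = [s for s in score_matrix.set_names if annotation.get(s) == PRO]
    if len(anti) < 2 or len(pro) < 2:
        raise ValueError("need at least 2 anti-tumor and 2 pro-tumor sets")
    anti_mean = score_matrix.scores.loc[anti].mean(axis=0)
    pro_mean = score_matrix.scores.loc[pro].mean(axis=0)
    out: dict[str, float] = {}
    for group in sorted(set(group_of[s] for s in score_matrix.sample_ids)):
        cols = [s for s in score_matrix.sample_ids if group_of[s] == group]
        if len(cols) < 3:
            raise ValueError(f"group {group!r} has fewer than 3 samples")
        a = anti_mean[cols].to_numpy(float)
        p = pro_mean[cols].to_numpy(float)
        if np.ptp(a) == 0 or np.ptp(p) == 0:
            raise ValueError(f"zero-variance score vector in group {group!r}")
        out[group] = float(stats.pearsonr(a, p).statistic)
    return out


def zscore_rows(score_matrix: ScoreMatrix) -> ScoreMatrix:
    """Standardize each set's row across samples (sample sd, ddof=1)."""
    df = score_matrix.scores
    sd = df.std(axis=1, ddof=1)
    constant = sd[(sd == 0) | ~np.isfinite(sd)].index.tolist()
    if constant:
        raise ValueError(f"constant score rows cannot be z-scored: {constant}")
    z = df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)
    return ScoreMatrix(z, "zscore")


def fisher_ora(
    hits,
    universe,
    annotation_sets: GeneSetCollection,
    *,
    adjust: bool = True,
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation of hits in each set.

    Sets are intersected with the universe; the 2x2 table per set is
    (hit-and-set, hit-not-set, set-not-hit, neither) and the p-value is the
    enrichment (greater) tail. Includes a Benjamini-Hochberg column unless
    ``adjust`` is off.
    """
    hits = set(hits)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    rows = []
    for name in annotation_sets.names():
        members = set(annotation_sets.sets[name]) & universe
        k = len(hits & members)
        n_hit, n_set, n_uni = len(hits), len(members), len(universe)
        table = [
            [k, n_hit - k],
            [n_set - k, n_uni - n_set - (n_hit - k)],
        ]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "set_name": name,
                "n_set": n_set,
                "n_overlap": k,
                "odds_ratio": float(odds),
                "p_value": float(p),
            }
        )
    out = pd.DataFrame.from_records(rows).set_index("set_name")
    if adjust and len(out):
        out["p_adj_bh"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out
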